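model,metric,fold,value
unet3d,dsc,1,0.723
unet3d,dsc,2,0.747
unet3d,dsc,3,0.784
unet3d,dsc,4,0.713
unet3d,dsc,5,0.721
unet3d,dsc,6,0.763
unet3d,iou,1,0.566
unet3d,iou,2,0.596
unet3d,iou,3,0.638
unet3d,iou,4,0.555
unet3d,iou,5,0.563
unet3d,iou,6,0.617
unet3d,sdsc,1,0.639
unet3d,sdsc,2,0.675
unet3d,sdsc,3,0.638
unet3d,sdsc,4,0.623
unet3d,sdsc,5,0.687
unet3d,sdsc,6,0.701
daf3d,dsc,1,0.835
daf3d,dsc,2,0.814
daf3d,dsc,3,0.801
daf3d,dsc,4,0.833
daf3d,dsc,5,0.788
daf3d,dsc,6,0.811
daf3d,iou,1,0.715
daf3d,iou,2,0.697
daf3d,iou,3,0.673
daf3d,iou,4,0.714
daf3d,iou,5,0.653
daf3d,iou,6,0.683
daf3d,sdsc,1,0.838
daf3d,sdsc,2,0.826
daf3d,sdsc,3,0.814
daf3d,sdsc,4,0.821
daf3d,sdsc,5,0.798
daf3d,sdsc,6,0.805
swin_unetr,dsc,1,0.829
swin_unetr,dsc,2,0.768
swin_unetr,dsc,3,0.802
swin_unetr,dsc,4,0.835
swin_unetr,dsc,5,0.831
swin_unetr,dsc,6,0.785
swin_unetr,iou,1,0.706
swin_unetr,iou,2,0.628
swin_unetr,iou,3,0.674
swin_unetr,iou,4,0.704
swin_unetr,iou,5,0.708
swin_unetr,iou,6,0.645
swin_unetr,sdsc,1,0.863
swin_unetr,sdsc,2,0.798
swin_unetr,sdsc,3,0.823
swin_unetr,sdsc,4,0.822
swin_unetr,sdsc,5,0.869
swin_unetr,sdsc,6,0.755
unetrpp,dsc,1,0.833
unetrpp,dsc,2,0.791
unetrpp,dsc,3,0.808
unetrpp,dsc,4,0.801
unetrpp,dsc,5,0.821
unetrpp,dsc,6,0.807
unetrpp,iou,1,0.711
unetrpp,iou,2,0.659
unetrpp,iou,3,0.685
unetrpp,iou,4,0.671
unetrpp,iou,5,0.701
unetrpp,iou,6,0.675
unetrpp,sdsc,1,0.876
unetrpp,sdsc,2,0.801
unetrpp,sdsc,3,0.818
unetrpp,sdsc,4,0.811
unetrpp,sdsc,5,0.857
unetrpp,sdsc,6,0.814
transunet,dsc,1,0.842
transunet,dsc,2,0.817
transunet,dsc,3,0.805
transunet,dsc,4,0.807
transunet,dsc,5,0.824
transunet,dsc,6,0.812
transunet,iou,1,0.722
transunet,iou,2,0.69
transunet,iou,3,0.674
transunet,iou,4,0.677
transunet,iou,5,0.703
transunet,iou,6,0.683
transunet,sdsc,1,0.823
transunet,sdsc,2,0.789
transunet,sdsc,3,0.796
transunet,sdsc,4,0.822
transunet,sdsc,5,0.831
transunet,sdsc,6,0.828
swindaf3d,dsc,1,0.854
swindaf3d,dsc,2,0.815
swindaf3d,dsc,3,0.841
swindaf3d,dsc,4,0.832
swindaf3d,dsc,5,0.849
swindaf3d,dsc,6,0.835
swindaf3d,iou,1,0.745
swindaf3d,iou,2,0.684
swindaf3d,iou,3,0.723
swindaf3d,iou,4,0.709
swindaf3d,iou,5,0.733
swindaf3d,iou,6,0.719
swindaf3d,sdsc,1,0.887
swindaf3d,sdsc,2,0.845
swindaf3d,sdsc,3,0.821
swindaf3d,sdsc,4,0.851
swindaf3d,sdsc,5,0.864
swindaf3d,sdsc,6,0.841
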