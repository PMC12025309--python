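"""Fold summaries and paired model comparison for cross-validation tables.

Summaries use the population (divide-by-n) standard deviation, the
convention under which the bundled benchmark table's printed Std rows are
reproduced exactly from their per-fold values.  Model comparison is the
Wilcoxon signed-rank test with an exact null distribution (all sign
assignments enumerated, midranks on tied absolute differences, zero
differences dropped) and Bonferroni correction for multiple comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import rankdata, wilcoxon as _scipy_wilcoxon

MODELS = ("unet3d", "daf3d", "swin_unetr", "unetrpp", "transunet", "swindaf3d")
METRICS = ("dsc", "iou", "sdsc")


@dataclass
class FoldSummary:
    mean: float
    std: float          # population convention

    def __post_init__(self):
        if self.std < 0:
            raise ValueError("std must be non-negative")


@dataclass
class ComparisonResult:
    statistic: float    # W = min(W+, W-)
    p_raw: float
    p_adjusted: float
    m: int
    sided: str
    n: int


def summarize_folds(values) -> FoldSummary:
    """Mean and population standard deviation of per-fold metric values."""
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size < 2:
        raise ValueError("need at least 2 fold values")
    return FoldSummary(mean=float(vals.mean()), std=float(vals.std(ddof=0)))


def wilcoxon_compare(values_a, values_b, m: int = 1, sided: str = "two",
                     max_exact_n: int = 20) -> ComparisonResult:
    """Paired signed-rank test between two models' per-fold metric values.

    ``sided='two'`` tests for any difference; ``sided='greater'`` for
    ``a > b``.  For up to ``max_exact_n`` non-zero differences the p-value is
    exact by enumerating all 2**n sign assignments; beyond that the normal
    approximation (via scipy) is used.  ``m`` is the Bonferroni multiplier.
    """
    if sided not in ("two", "greater", "less"):
        raise ValueError("sided must be 'two', 'greater' or 'less'")
    if m < 1:
        raise ValueError("m must be >= 1")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1D sequences")
    diffs = a - b
    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n == 0:
        return ComparisonResult(statistic=0.0, p_raw=1.0, p_adjusted=1.0,
                                m=m, sided=sided, n=0)
    ranks = rankdata(np.abs(diffs))           # midranks on ties
    w_plus = float(ranks[diffs > 0].sum())
    w_minus = float(ranks[diffs < 0].sum())
    w_min = min(w_plus, w_minus)

    if n <= max_exact_n:
        total = 2 ** n
        count = 0
        rank_list = ranks.tolist()
        for signs in product((0, 1), repeat=n):
            wp = sum(r for s, r in zip(signs, rank_list) if s)
            if sided == "two":
                wm = sum(rank_list) - wp
                if min(wp, wm) <= w_min:
                    count += 1
            elif sided == "greater":
                if wp >= w_plus:
                    count += 1
            else:
                if wp <= w_plus:
                    count += 1
        p = count / total
    else:
        alt = {"two": "two-sided", "greater": "greater", "less": "less"}[sided]
        p = float(_scipy_wilcoxon(a, b, alternative=alt, method="approx").pvalue)

    return ComparisonResult(statistic=w_min, p_raw=p, p_adjusted=min(1.0, m * p),
                            m=m, sided=sided, n=n)


class FoldTable:
    """Per-fold metric values for one or more models (long-format table)."""

    def __init__(self, frame: pd.DataFrame):
        required = {"model", "metric", "fold", "value"}
        if not required <= set(frame.columns):
            raise ValueError(f"fold table needs columns {sorted(required)}")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_dict(cls, data: dict) -> "FoldTable":
        rows = [(model, metric, fold, val)
                for model, mets in data.items()
                for metric, vals in mets.items()
                for fold, val in enumerate(vals, start=1)]
        return cls(pd.DataFrame(rows, columns=["model", "metric", "fold", "value"]))

    def models(self):
        return list(dict.fromkeys(self.frame["model"]))

    def metrics(self):
        return list(dict.fromkeys(self.frame["metric"]))

    def values(self, model: str, metric: str) -> np.ndarray:
        sel = self.frame[(self.frame["model"] == model) & (self.frame["metric"] == metric)]
        if sel.empty:
            raise KeyError(f"no fold values for ({model}, {metric})")
        return sel.sort_values("fold")["value"].to_numpy(dtype=float)

    def summarize(self, model: str, metric: str) -> FoldSummary:
        return summarize_folds(self.values(model, metric))

    def summary_table(self) -> pd.DataFrame:
        """Mean/Std rows per model and metric, mirroring a cross-validation table."""
        rows = []
        for model in self.models():
            for metric in self.metrics():
                s = self.summarize(model, metric)
                rows.append((model, metric, s.mean, s.std))
        return pd.DataFrame(rows, columns=["model", "metric", "mean", "std"])

    def compare(self, model_a: str, model_b: str, metric: str, m: int = 1,
                sided: str = "two") -> ComparisonResult:
        va, vb = self.values(model_a, metric), self.values(model_b, metric)
        if va.size != vb.size:
            raise ValueError("models have different fold counts")
        return wilcoxon_compare(va, vb, m=m, sided=sided)


def load_benchmark_folds() -> FoldTable:
    """The bundled six-fold benchmark table for the six ablation models."""
    with resources.files("swindaf3d.data").joinpath("benchmark_folds.csv").open() as fh:
        return FoldTable(pd.read_csv(fh))
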