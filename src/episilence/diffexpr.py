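"""Driver median split, two-group differential expression, k-group
comparisons, and pairwise correlation analyses.

Expression is on the log2(1+x) scale throughout, so the fold change is
2**(mean difference of log values). Two test backends are available
(Welch t, default, or Mann-Whitney); Benjamini-Hochberg controls the FDR
across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, PipelineConfig, ValidationError


def split_by_driver(expr: ExpressionMatrix, driver_gene: str) -> dict[str, str]:
    """Median split on the driver gene: strictly above the median -> "high",
    at or below -> "low"."""
    if driver_gene not in expr.df.index:
        raise ValidationError(f"driver gene {driver_gene!r} absent from expression")
    v = expr.df.loc[driver_gene].to_numpy(float)
    if np.ptp(v) == 0:
        raise ValidationError(f"driver gene {driver_gene!r} has constant expression; "
                              "median split is degenerate")
    med = float(np.median(v))
    groups = {s: ("high" if x > med else "low")
              for s, x in zip(expr.df.columns, v)}
    if "high" not in groups.values() or "low" not in groups.values():
        raise ValidationError("median split produced an empty group")
    return groups


def differential_expression(expr: ExpressionMatrix, groups: dict[str, str],
                            config: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-gene two-group test with BH adjustment and symmetric fold-change
    calls. Columns: gene, log2_fc (mean high - mean low), fold_change,
    p_value, p_adj, call in {up, down, ns}."""
    config = config or PipelineConfig()
    samples = list(expr.df.columns)
    g = np.array([groups[s] == "high" for s in samples])
    if g.sum() < 2 or (~g).sum() < 2:
        raise ValidationError("need >= 2 samples per group")
    x = expr.df.to_numpy()
    hi, lo = x[:, g], x[:, ~g]
    log2_fc = hi.mean(axis=1) - lo.mean(axis=1)

    if config.de_test == "welch_t":
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(hi, lo, axis=1, equal_var=False)
            p = np.asarray(res.pvalue)
        zero_var = (hi.std(axis=1) == 0) & (lo.std(axis=1) == 0)
        p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    else:
        p = np.empty(x.shape[0])
        for i in range(x.shape[0]):
            if np.ptp(x[i]) == 0:
                p[i] = 1.0
            else:
                p[i] = stats.mannwhitneyu(hi[i], lo[i],
                                          alternative="two-sided").pvalue
    p_adj = multipletests(p, method="fdr_bh")[1]

    fc = 2.0 ** log2_fc
    call = np.full(len(fc), "ns", dtype=object)
    sig = p_adj < config.de_adj_p
    call[sig & (fc >= config.de_fc_threshold)] = "up"
    call[sig & (fc <= 1.0 / config.de_fc_threshold)] = "down"
    return pd.DataFrame({
        "gene": expr.df.index,
        "log2_fc": log2_fc,
        "fold_change": fc,
        "p_value": p,
        "p_adj": p_adj,
        "call": call,
    }).reset_index(drop=True)


def intersect_silenced(hypermethylated: dict, de_results: pd.DataFrame) -> list[str]:
    """Genes both promoter-hypermethylated and downregulated, sorted by the
    best supporting DMR Sidak p (then symbol for determinism)."""
    down = set(de_results.loc[de_results["call"] == "down", "gene"])
    hyper = {g: c for g, c in hypermethylated.items()
             if getattr(c, "hypermethylated", bool(c))}
    both = down & set(hyper)
    def key(g: str):
        call = hyper[g]
        best = getattr(call, "best_p_sidak", 0.0)
        return (best, g)
    return sorted(both, key=key)


def group_compare(*groups: np.ndarray) -> tuple[float, float]:
    """k=2 -> two-tailed pooled-variance t; k>2 -> one-way ANOVA (F, p)."""
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValidationError("each group needs >= 2 values")
    if len(arrays) == 2:
        if all(np.ptp(a) == 0 for a in arrays) and arrays[0].mean() == arrays[1].mean():
            return 0.0, 1.0
        res = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
        return float(res.statistic), float(res.pvalue)
    res = stats.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CorrelationResult:
    label_x: str
    label_y: str
    pearson_r: float
    p_value: float
    n: int


def correlate(x: np.ndarray, y: np.ndarray,
              label_x: str = "x", label_y: str = "y") -> CorrelationResult:
    """Pearson correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValidationError("need n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("undefined correlation: zero variance input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(label_x, label_y, float(r), float(p), len(x))


def promoter_mean_beta(beta, manifest, gene: str) -> pd.Series:
    """Per-sample mean beta over the gene's promoter-class probes."""
    from .io import PROMOTER_CLASSES
    probes = [r.probe_id for r in manifest
              if any(g == gene and c in PROMOTER_CLASSES for g, c in r.annotations)]
    if not probes:
        raise ValidationError(f"no promoter-class probes annotated to {gene!r}")
    return beta.df.loc[probes].mean(axis=0, skipna=True)
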