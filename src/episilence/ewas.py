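"""Per-probe EWAS and the combined-p DMR caller.

The EWAS regresses each probe's beta values on a 0/1 driver-group indicator
(ordinary least squares; two-sided p from the t distribution with n-2 df,
algebraically the equal-variance two-sample t-test). Per-probe p-values are
then aggregated into differentially methylated regions with an
autocorrelation-corrected Stouffer-Liptak combination:

1. estimate the autocorrelation of probit scores z = Phi^-1(1-p) as a
   function of genomic lag (binned, clipped to [0, 0.99]);
2. slide a +-dist/2 window over each probe and replace its p by the
   Stouffer-Liptak combination of the window, with the pairwise correlation
   sigma_ij read from the ACF bin of |pos_i - pos_j|;
3. grow regions from seed probes (adjusted p < seed_p) over consecutive
   probes below region_filter_p with inter-probe gaps <= dist, discarding
   regions with fewer than region_filter_n probes;
4. score each region by Stouffer-Liptak over the raw member p-values and
   apply a Sidak correction with exponent B/w, where w is the region span
   and B the total genomic span of tested probes;
5. assign hypermethylated regions (Sidak p below a gene-level threshold) to
   genes via promoter-class probe annotations (TSS200/TSS1500/5UTR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import PROMOTER_CLASSES, PipelineConfig, ProbeManifest, ValidationError

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


# ---------------------------------------------------------------------------
# EWAS
# ---------------------------------------------------------------------------

def ewas(beta, groups: Mapping[str, str], manifest: ProbeManifest) -> pd.DataFrame:
    """Per-probe OLS of beta on the high/low indicator.

    Returns a genome-sorted DataFrame with columns probe_id, chrom, pos,
    delta_beta (mean high - mean low), t_stat, p_value, flag. Probes with
    fewer than two usable samples in either group are kept with p = 1 and
    flag = "insufficient_data"; zero-variance probes get delta_beta = 0,
    p = 1.
    """
    df = beta.df
    g = np.array([1.0 if groups[s] == "high" else 0.0 for s in df.columns])
    if g.sum() < 2 or (1 - g).sum() < 2:
        raise ValidationError("need >= 2 samples per group")
    x = df.to_numpy()
    ok = ~np.isnan(x)
    xz = np.where(ok, x, 0.0)

    n1 = ok @ g
    n0 = ok @ (1.0 - g)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = (xz @ g) / n1
        m0 = (xz @ (1.0 - g)) / n0
        ss1 = (xz**2) @ g - n1 * m1**2
        ss0 = (xz**2) @ (1.0 - g) - n0 * m0**2
        df_t = n1 + n0 - 2
        sp2 = np.maximum(ss1 + ss0, 0.0) / np.maximum(df_t, 1)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n0))
        t = (m1 - m0) / se

    delta = m1 - m0
    p = np.ones_like(delta)
    flag = np.full(len(delta), "", dtype=object)

    insufficient = (n1 < 2) | (n0 < 2)
    flag[insufficient] = "insufficient_data"
    delta = np.where(insufficient, np.where(np.isfinite(delta), delta, 0.0), delta)

    usable = ~insufficient
    zero_var = usable & (sp2 <= 0)
    sep = zero_var & (np.abs(delta) > 0)  # perfect separation: means differ, no spread
    delta = np.where(zero_var & ~sep, 0.0, delta)
    with np.errstate(invalid="ignore"):
        t = np.where(zero_var, np.where(sep, np.sign(delta) * np.inf, 0.0), t)
    normal = usable & ~zero_var
    p[normal] = 2.0 * stats.t.sf(np.abs(t[normal]), df_t[normal])
    p[sep] = _P_FLOOR
    p = np.clip(p, _P_FLOOR, 1.0)
    t = np.where(np.isfinite(t), t, np.sign(delta) * 1e9)

    order = {pid: i for i, pid in enumerate(df.index)}
    rows = [(r.probe_id, r.chrom, r.pos) for r in manifest if r.probe_id in order]
    idx = np.array([order[pid] for pid, _, _ in rows])
    out = pd.DataFrame({
        "probe_id": [r[0] for r in rows],
        "chrom": [r[1] for r in rows],
        "pos": np.array([r[2] for r in rows], dtype=np.int64),
        "delta_beta": delta[idx],
        "t_stat": t[idx],
        "p_value": p[idx],
        "flag": flag[idx],
    })
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# ACF of probit scores vs genomic lag
# ---------------------------------------------------------------------------

@dataclass
class AcfEstimate:
    """Binned lag correlation of probit scores; bin k covers (k*step, (k+1)*step]."""

    step: int
    max_lag: int
    rho: np.ndarray          # per-bin correlation, clipped to [0, 0.99]
    counts: np.ndarray       # per-bin pair counts
    degenerate: bool = False

    def sigma(self, lag_bp: int | np.ndarray) -> np.ndarray:
        """Correlation at a genomic lag; lag 0 is 1 by definition."""
        lag = np.asarray(lag_bp, dtype=np.int64)
        k = np.clip((lag - 1) // self.step, 0, len(self.rho) - 1)
        return np.where(lag == 0, 1.0, self.rho[k])

    def sigma_matrix(self, positions: np.ndarray) -> np.ndarray:
        d = np.abs(positions[:, None] - positions[None, :])
        return self.sigma(d)


def _probit(p: np.ndarray) -> np.ndarray:
    return stats.norm.isf(np.clip(p, _P_FLOOR, _P_CEIL))


def estimate_acf(results: pd.DataFrame, max_lag: int = 1000,
                 step: int = 50, min_pairs: int = 10) -> AcfEstimate:
    """Per-lag-bin Pearson correlation of probit scores over same-chromosome
    probe pairs. Bins with fewer than ``min_pairs`` pairs inherit the nearest
    populated bin's value; an input with no score variance at all yields the
    flagged degenerate fallback rho = 0.99 everywhere."""
    nbins = int(np.ceil(max_lag / step))
    z_all = _probit(results["p_value"].to_numpy())
    sums = np.zeros((nbins, 5))  # sx, sy, sxx, syy, sxy
    counts = np.zeros(nbins, dtype=np.int64)
    for _, grp in results.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(np.int64)
        z = z_all[grp.index.to_numpy()]
        n = len(pos)
        off = 1
        while off < n:
            d = pos[off:] - pos[:-off]
            sel = d <= max_lag
            if not sel.any():
                break
            k = (d[sel] - 1) // step
            zi, zj = z[:-off][sel], z[off:][sel]
            np.add.at(counts, k, 1)
            np.add.at(sums[:, 0], k, zi)
            np.add.at(sums[:, 1], k, zj)
            np.add.at(sums[:, 2], k, zi * zi)
            np.add.at(sums[:, 3], k, zj * zj)
            np.add.at(sums[:, 4], k, zi * zj)
            off += 1
    if counts.sum() == 0:
        raise ValidationError("no same-chromosome probe pairs within max_lag; "
                              "provide denser data or inject a fixed ACF")
    rho = np.full(nbins, np.nan)
    degenerate = False
    for k in range(nbins):
        if counts[k] < min_pairs:
            continue
        n = counts[k]
        sx, sy, sxx, syy, sxy = sums[k]
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        if vx <= 0 or vy <= 0:
            rho[k] = 0.99  # identical scores: correlation undefined, assume max
            degenerate = True
            continue
        rho[k] = np.clip((sxy - sx * sy / n) / np.sqrt(vx * vy), 0.0, 0.99)
    populated = np.nonzero(~np.isnan(rho))[0]
    if populated.size == 0:
        raise ValidationError(
            f"fewer than {min_pairs} probe pairs in every lag bin; "
            "provide larger data or inject a fixed ACF")
    for k in range(nbins):
        if np.isnan(rho[k]):
            rho[k] = rho[populated[np.argmin(np.abs(populated - k))]]
    return AcfEstimate(step=step, max_lag=max_lag, rho=rho, counts=counts,
                       degenerate=degenerate)


# ---------------------------------------------------------------------------
# Stouffer-Liptak combination
# ---------------------------------------------------------------------------

def stouffer_liptak(p: Sequence[float] | np.ndarray,
                    sigma: np.ndarray) -> float:
    """Correlation-corrected Stouffer combination:
    z_comb = sum(Phi^-1(1-p_i)) / sqrt(sum_ij sigma_ij)."""
    p = np.asarray(p, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (p.size, p.size):
        raise ValueError("sigma must be k x k for k p-values")
    denom = sigma.sum()
    if denom <= 0:
        raise ValidationError("sum of correlation matrix is non-positive")
    z = _probit(p)
    return float(stats.norm.sf(z.sum() / np.sqrt(denom)))


def sliding_window_adjust(results: pd.DataFrame, acf: AcfEstimate,
                          dist: int = 1000) -> pd.DataFrame:
    """Replace each probe's p by the Stouffer-Liptak combination of all
    same-chromosome probes within +-dist/2 bp. Probes with no neighbours
    keep their raw p exactly."""
    half = dist / 2.0
    p_adj = np.empty(len(results))
    raw = results["p_value"].to_numpy()
    z_all = _probit(raw)
    for _, grp in results.groupby("chrom", sort=False):
        gi = grp.index.to_numpy()
        pos = grp["pos"].to_numpy(np.int64)
        z = z_all[gi]
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        for j in range(len(pos)):
            a, b = lo[j], hi[j]
            if b - a <= 1:
                p_adj[gi[j]] = raw[gi[j]]
                continue
            w_pos = pos[a:b]
            sig = acf.sigma(np.abs(w_pos[:, None] - w_pos[None, :]))
            p_adj[gi[j]] = stats.norm.sf(z[a:b].sum() / np.sqrt(sig.sum()))
    out = results.copy()
    out["p_adjusted"] = np.clip(p_adj, _P_FLOOR, 1.0)
    return out


# ---------------------------------------------------------------------------
# Region finding and scoring
# ---------------------------------------------------------------------------

@dataclass
class DmrRecord:
    """A called region; BED-style 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    probe_ids: list[str]
    direction: str  # "hyper" | "hypo"
    p_combined: float = float("nan")
    p_sidak: float = float("nan")
    assigned_genes: set[tuple[str, str]] = field(default_factory=set)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def find_regions(adjusted: pd.DataFrame, seed_p: float = 1e-5,
                 dist: int = 1000, region_filter_p: float = 0.05,
                 region_filter_n: int = 2) -> list[DmrRecord]:
    """Grow regions from seed probes (adjusted p < seed_p) over consecutive
    probes with adjusted p < region_filter_p and inter-probe gaps <= dist;
    drop regions with fewer than region_filter_n probes."""
    regions: list[DmrRecord] = []
    for chrom, grp in adjusted.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(np.int64)
        padj = grp["p_adjusted"].to_numpy()
        delta = grp["delta_beta"].to_numpy()
        pid = grp["probe_id"].to_numpy()
        candidate = padj < region_filter_p
        n = len(pos)
        i = 0
        while i < n:
            if not candidate[i]:
                i += 1
                continue
            j = i
            while (j + 1 < n and candidate[j + 1]
                   and pos[j + 1] - pos[j] <= dist):
                j += 1
            members = slice(i, j + 1)
            if (padj[members] < seed_p).any() and (j - i + 1) >= region_filter_n:
                mean_delta = float(delta[members].mean())
                regions.append(DmrRecord(
                    chrom=chrom,
                    start=int(pos[i]) - 1,
                    end=int(pos[j]),
                    probe_ids=list(pid[members]),
                    direction="hyper" if mean_delta > 0 else "hypo",
                ))
            i = j + 1
    return regions


def total_tested_bases(results: pd.DataFrame) -> int:
    """Sum over chromosomes of (max pos - min pos) for tested probes."""
    span = results.groupby("chrom")["pos"].agg(lambda s: s.max() - s.min())
    return int(span.sum())


def score_region(region: DmrRecord, results: pd.DataFrame, acf: AcfEstimate,
                 total_bases: int | None = None) -> tuple[float, float]:
    """Stouffer-Liptak over the raw member p-values, then Sidak correction
    with exponent B/w (floored at 1)."""
    if total_bases is None:
        total_bases = total_tested_bases(results)
    sub = results.set_index("probe_id").loc[region.probe_ids]
    pos = sub["pos"].to_numpy(np.int64)
    p_comb = stouffer_liptak(sub["p_value"].to_numpy(), acf.sigma_matrix(pos))
    w = max(region.end - region.start, 1)
    expo = max(total_bases / w, 1.0)
    p_sidak = float(-np.expm1(expo * np.log1p(-min(p_comb, _P_CEIL))))
    return p_comb, min(max(p_sidak, p_comb), 1.0)


@dataclass
class GeneMethylationCall:
    gene: str
    hypermethylated: bool
    best_p_sidak: float
    supporting_regions: list[DmrRecord]


def assign_regions_to_genes(dmrs: list[DmrRecord], manifest: ProbeManifest,
                            gene_dmr_p: float = 1e-5) -> dict[str, GeneMethylationCall]:
    """Gene-level calls: a gene is hypermethylated iff some hyper-direction
    DMR with Sidak p below threshold contains a probe annotated to it with a
    promoter class (TSS200/TSS1500/5UTR). Every DMR also gets its full
    (gene, region_class) annotation fan-out attached."""
    calls: dict[str, GeneMethylationCall] = {}
    for dmr in dmrs:
        pairs: set[tuple[str, str]] = set()
        for pid in dmr.probe_ids:
            pairs |= set(manifest[pid].annotations)
        dmr.assigned_genes = pairs
        if dmr.direction != "hyper" or not (dmr.p_sidak < gene_dmr_p):
            continue
        for gene, cls in pairs:
            if cls not in PROMOTER_CLASSES:
                continue
            call = calls.get(gene)
            if call is None:
                calls[gene] = GeneMethylationCall(gene, True, dmr.p_sidak, [dmr])
            else:
                call.supporting_regions.append(dmr)
                call.best_p_sidak = min(call.best_p_sidak, dmr.p_sidak)
    return calls


def call_dmrs(results: pd.DataFrame, manifest: ProbeManifest,
              config: PipelineConfig | None = None,
              acf: AcfEstimate | None = None,
              ) -> tuple[list[DmrRecord], dict[str, GeneMethylationCall]]:
    """Full combined-p cascade: ACF -> window adjustment -> region growth ->
    region scoring -> promoter gene assignment."""
    config = config or PipelineConfig()
    if acf is None:
        acf = estimate_acf(results, max_lag=config.dmr_dist)
    adjusted = sliding_window_adjust(results, acf, dist=config.dmr_dist)
    regions = find_regions(adjusted, seed_p=config.dmr_seed_p,
                           dist=config.dmr_dist,
                           region_filter_p=config.dmr_region_filter_p,
                           region_filter_n=config.dmr_region_filter_n)
    b = total_tested_bases(results)
    indexed = results.set_index("probe_id")
    for region in regions:
        sub = indexed.loc[region.probe_ids]
        pos = sub["pos"].to_numpy(np.int64)
        p_comb = stouffer_liptak(sub["p_value"].to_numpy(), acf.sigma_matrix(pos))
        w = max(region.end - region.start, 1)
        expo = max(b / w, 1.0)
        p_sidak = float(-np.expm1(expo * np.log1p(-min(p_comb, _P_CEIL))))
        region.p_combined = p_comb
        region.p_sidak = min(max(p_sidak, p_comb), 1.0)
    genes = assign_regions_to_genes(regions, manifest, config.gene_dmr_p)
    return regions, genes
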