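"""Native survival machinery: Kaplan-Meier product-limit estimation,
two-group log-rank test, Cox proportional-hazards fitting (Newton-Raphson
on the Breslow- or Efron-ties partial likelihood), and the >= k-of-n
multi-cohort consensus screen.

Conventions: a sample censored at an event time is at risk through that
time; the Cox covariate is standardized continuous expression, so the
hazard ratio is per one standard deviation, and hr < 1 means higher
expression is protective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortBundle, PipelineConfig, ValidationError


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KmCurve:
    event_times: np.ndarray   # distinct event times, sorted
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray      # S(t) just after each event time
    censor_times: np.ndarray

    def step(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KmCurve:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("empty survival input")
    if (times <= 0).any():
        raise ValidationError("survival times must be > 0")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq = np.unique(t[e == 1])
    n = len(t)
    at_risk = np.empty(len(uniq), dtype=int)
    d = np.empty(len(uniq), dtype=int)
    surv = np.empty(len(uniq))
    s = 1.0
    for i, u in enumerate(uniq):
        at_risk[i] = int((t >= u).sum())
        d[i] = int(((t == u) & (e == 1)).sum())
        s *= 1.0 - d[i] / at_risk[i]
        surv[i] = s
    return KmCurve(uniq, at_risk, d, surv, np.sort(t[e == 0]))


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def logrank_test(group_a: tuple[Sequence[float], Sequence[int]],
                 group_b: tuple[Sequence[float], Sequence[int]]) -> tuple[float, float]:
    """Two-group log-rank with hypergeometric variance at each distinct
    event time; returns (chi2, p) on 1 df."""
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], int)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], int)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups must be non-empty")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(ta.size, dtype=int), np.ones(tb.size, dtype=int)])
    if e.sum() == 0:
        raise ValidationError("no events in either group")
    event_times = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    for u in event_times:
        at = t >= u
        n = at.sum()
        n1 = (at & (grp == 0)).sum()
        dead = (t == u) & (e == 1)
        d = dead.sum()
        d1 = (dead & (grp == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Cox proportional hazards (single covariate)
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    beta: float
    hr: float
    se: float
    p: float
    converged: bool
    n: int
    n_events: int

    @property
    def ok(self) -> bool:
        return self.converged and np.isfinite(self.p)


def _cox_derivatives(beta: float, times: np.ndarray, events: np.ndarray,
                     x: np.ndarray, ties: str) -> tuple[float, float, float]:
    """(log-likelihood, score, information) of the partial likelihood."""
    order = np.argsort(-times, kind="stable")  # decreasing time
    t, e, xv = times[order], events[order], x[order]
    theta = np.exp(beta * xv)
    # cumulative risk-set sums walking from the latest time down
    s0 = np.cumsum(theta)
    s1 = np.cumsum(theta * xv)
    s2 = np.cumsum(theta * xv * xv)
    loglik = score = info = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        dead = np.nonzero(e[i:j + 1] == 1)[0] + i
        d = len(dead)
        if d:
            r0, r1, r2 = s0[j], s1[j], s2[j]
            sx = xv[dead].sum()
            if ties == "breslow" or d == 1:
                loglik += beta * sx - d * np.log(r0)
                score += sx - d * r1 / r0
                info += d * (r2 / r0 - (r1 / r0) ** 2)
            else:  # efron
                td0 = theta[dead].sum()
                td1 = (theta[dead] * xv[dead]).sum()
                td2 = (theta[dead] * xv[dead] ** 2).sum()
                for k in range(d):
                    f = k / d
                    a0 = r0 - f * td0
                    a1 = r1 - f * td1
                    a2 = r2 - f * td2
                    loglik += -np.log(a0)
                    score += -a1 / a0
                    info += a2 / a0 - (a1 / a0) ** 2
                loglik += beta * sx
                score += sx
        i = j + 1
    return loglik, score, info


def cox_fit(times: Sequence[float], events: Sequence[int],
            covariate: Sequence[float], ties: str = "breslow",
            tol: float = 1e-9, max_iter: int = 50,
            standardize: bool = True) -> CoxResult:
    """Single-covariate Cox PH via Newton-Raphson with step-halving.

    The covariate is standardized by default, so beta (and hr = exp(beta))
    are per 1 SD. Non-convergence or monotone-likelihood separation yields
    a flagged result with p = NaN.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(covariate, float)
    if events.sum() < 2:
        raise ValidationError("need >= 2 events to fit a Cox model")
    sd = x.std()
    if sd == 0:
        raise ValidationError("covariate variance must be > 0")
    if standardize:
        x = (x - x.mean()) / sd
    if ties not in {"breslow", "efron"}:
        raise ValueError(f"unknown tie handling {ties!r}")

    beta = 0.0
    loglik, score, info = _cox_derivatives(beta, times, events, x, ties)
    converged = False
    for _ in range(max_iter):
        if info <= 0:
            break
        step = score / info
        new_beta = beta + step
        # step-halving keeps the likelihood ascending
        for _ in range(30):
            new_ll, new_sc, new_in = _cox_derivatives(new_beta, times, events, x, ties)
            if new_ll >= loglik - 1e-12:
                break
            new_beta = (beta + new_beta) / 2.0
        if abs(new_beta - beta) < tol:
            beta, loglik, score, info = new_beta, new_ll, new_sc, new_in
            converged = True
            break
        beta, loglik, score, info = new_beta, new_ll, new_sc, new_in
    separated = abs(beta) > 20
    if converged and not separated and info > 0:
        se = float(1.0 / np.sqrt(info))
        z = beta / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        se, p, converged = float("nan"), float("nan"), False
    return CoxResult(beta=float(beta), hr=float(np.exp(beta)), se=se, p=p,
                     converged=converged, n=len(times), n_events=int(events.sum()))


# ---------------------------------------------------------------------------
# Multi-cohort gene screen + consensus
# ---------------------------------------------------------------------------

@dataclass
class GeneSurvivalResult:
    gene: str
    cohort_id: str
    hr: float
    cox_p: float
    logrank_p: float
    n: int
    n_events: int
    note: str = ""

    def significant(self, alpha: float) -> bool:
        return (np.isfinite(self.cox_p) and np.isfinite(self.logrank_p)
                and self.cox_p < alpha and self.logrank_p < alpha
                and self.hr < 1.0)


@dataclass
class ConsensusCall:
    gene: str
    n_significant_cohorts: int
    passes: bool
    per_cohort: list[GeneSurvivalResult] = field(default_factory=list)


def gene_survival_screen(cohorts: Sequence[CohortBundle], genes: Sequence[str],
                         config: PipelineConfig | None = None,
                         ) -> tuple[list[GeneSurvivalResult], list[ConsensusCall]]:
    """Per gene per cohort: Cox on standardized continuous expression and a
    log-rank test on the gene's median split. A gene passes consensus when
    Cox p and log-rank p are both below alpha with hr < 1 in at least
    ``consensus_min_cohorts`` cohorts. No cross-gene multiplicity
    correction is applied; replication across cohorts is the guard."""
    config = config or PipelineConfig()
    results: list[GeneSurvivalResult] = []
    calls: list[ConsensusCall] = []
    for gene in genes:
        per_gene: list[GeneSurvivalResult] = []
        for bundle in cohorts:
            res = _screen_one(bundle, gene, config)
            per_gene.append(res)
            results.append(res)
        n_sig = sum(r.significant(config.survival_alpha) for r in per_gene)
        calls.append(ConsensusCall(gene, n_sig,
                                   n_sig >= config.consensus_min_cohorts, per_gene))
    return results, calls


def _screen_one(bundle: CohortBundle, gene: str,
                config: PipelineConfig) -> GeneSurvivalResult:
    nan = float("nan")
    if gene not in bundle.expression.df.index:
        return GeneSurvivalResult(gene, bundle.cohort_id, nan, nan, nan, 0, 0,
                                  note="gene_absent")
    samples = bundle.expression.sample_ids
    x = bundle.expression.df.loc[gene].to_numpy(float)
    times, events = bundle.clinical.times_events(samples)
    if x.std() == 0 or events.sum() < 2:
        return GeneSurvivalResult(gene, bundle.cohort_id, nan, nan, nan,
                                  len(samples), int(events.sum()),
                                  note="degenerate")
    try:
        cox = cox_fit(times, events, x)
    except ValidationError:
        return GeneSurvivalResult(gene, bundle.cohort_id, nan, nan, nan,
                                  len(samples), int(events.sum()), note="cox_failed")
    med = np.median(x)
    hi = x > med
    if hi.sum() == 0 or (~hi).sum() == 0:
        lr_p = nan
        note = "degenerate_split"
    else:
        try:
            _, lr_p = logrank_test((times[hi], events[hi]), (times[~hi], events[~hi]))
            note = "" if cox.ok else "cox_not_converged"
        except ValidationError:
            lr_p, note = nan, "logrank_failed"
    return GeneSurvivalResult(gene, bundle.cohort_id,
                              cox.hr if cox.ok else nan,
                              cox.p, lr_p, cox.n, cox.n_events, note=note)


def survival_results_frame(results: Sequence[GeneSurvivalResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": r.gene, "cohort": r.cohort_id, "hr": r.hr,
        "log2_hr": np.log2(r.hr) if r.hr > 0 else float("nan"),
        "cox_p": r.cox_p, "logrank_p": r.logrank_p,
        "n": r.n, "n_events": r.n_events, "note": r.note,
    } for r in results])
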