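"""Severity-stratified cohort statistics.

Implements the study-style statistical workflow: heart-to-body-weight-ratio
(HBWR) severity stratification of shunted animals, group mean ± SD
summaries, one-way ANOVA with Dunnett many-to-one post-hoc comparisons
against the sham control, and Pearson correlation with a least-squares
line.

The Dunnett adjusted p-values are computed from the equicoordinate box
probability of the multivariate t distribution of the maximum |statistic|
(numerical integration via scipy's multivariate t CDF with a fixed QMC
seed); the single-treatment case reduces exactly to the pooled two-sample
t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

__all__ = [
    "SeverityAssignment", "GroupSummary", "CorrResult", "DunnettResult",
    "assign_severity", "group_summary", "anova_oneway", "dunnett",
    "dunnett_critical_value", "pearson", "HBWR_CUTS", "FAILING_LUNGS_BW",
]

# HBWR cut points: the published per-group ranges leave gaps 4.88→5.19 and
# 5.73→5.99; defaults are the gap midpoints.
HBWR_CUTS = (5.035, 5.86)
# lungs/BW boundary between compensated and failing; >= 5 g/kg counts as failing
FAILING_LUNGS_BW = 5.0


@dataclass
class SeverityAssignment:
    label: str                       # sham | mild | moderate | severe
    failing: bool | None             # None if lungs weight missing


@dataclass
class DunnettResult:
    comparisons: list[str]           # group labels compared against control
    estimates: np.ndarray            # mean difference vs. control
    statistics: np.ndarray
    p_adjusted: np.ndarray
    p_unadjusted: np.ndarray
    df: int


@dataclass
class GroupSummary:
    table: pd.DataFrame              # per (variable, group): mean, sd, n
    anova_p: dict[str, float]
    dunnett_p: dict[str, dict[str, float]]   # variable -> group -> adjusted p
    notes: list[str] = field(default_factory=list)


@dataclass
class CorrResult:
    r: float
    p_value: float
    n: int
    slope: float
    intercept: float


def assign_severity(cohort: str, hbwr: float,
                    lungs_bw: float | None = None,
                    cuts: tuple[float, float] = HBWR_CUTS) -> SeverityAssignment:
    """Severity label from HBWR (g/kg) and failing status from lungs/BW.

    Sham animals keep the label ``sham``; shunted (ACF) animals are mild
    below ``cuts[0]``, moderate below ``cuts[1]``, severe otherwise.
    ``failing`` is lungs/BW >= 5 g/kg, or None (with a log warning) if the
    lungs weight is unavailable.
    """
    if not np.isfinite(hbwr):
        raise ValueError("hbwr must be finite")
    if cohort == "sham":
        label = "sham"
    else:
        label = ("mild" if hbwr < cuts[0]
                 else "moderate" if hbwr < cuts[1]
                 else "severe")
    if lungs_bw is None or not np.isfinite(lungs_bw):
        logger.warning("lungs weight missing; failing status unavailable")
        failing = None
    else:
        failing = bool(lungs_bw >= FAILING_LUNGS_BW)
    return SeverityAssignment(label=label, failing=failing)


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparisons
# ---------------------------------------------------------------------------

def _dunnett_corr(ns: np.ndarray, n0: int) -> np.ndarray:
    lam = np.sqrt(ns / (ns + n0))
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)
    return corr


def _max_abs_le(c: float, corr: np.ndarray, df: int, seed: int = 0) -> float:
    """P(max_i |T_i| <= c) for an equicorrelated-by-design multivariate t."""
    k = corr.shape[0]
    if k == 1:
        return float(1.0 - 2.0 * sstats.t.sf(c, df))
    mvt = sstats.multivariate_t(loc=np.zeros(k), shape=corr, df=df)
    val = mvt.cdf(np.full(k, c), lower_limit=np.full(k, -c),
                  random_state=np.random.default_rng(seed), maxpts=200_000 * k)
    return float(val)


def dunnett(values: np.ndarray, groups: np.ndarray, control_label,
            alpha: float = 0.05) -> DunnettResult:
    """Two-sided Dunnett many-to-one comparisons with pooled variance.

    Adjusted p for comparison i is 1 − P(max_j |T_j| ≤ |t_i|) under the
    joint null multivariate t.  ``alpha`` is carried for interface
    compatibility with confidence-limit extensions; p-values do not depend
    on it.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups) if g != control_label]
    if control_label not in set(groups.tolist()):
        raise ValueError(f"control group {control_label!r} not present")
    if len(labels) < 1:
        raise ValueError("need at least one treatment group besides control")
    x0 = values[groups == control_label]
    if x0.size < 2:
        raise ValueError("control group needs n >= 2")

    xs = [values[groups == g] for g in labels]
    ns = np.array([x.size for x in xs])
    n0 = x0.size
    n_tot = n0 + ns.sum()
    k = len(xs)
    df = int(n_tot - (k + 1))
    if df < 1:
        raise ValueError("not enough observations for a pooled variance")
    ss = np.sum((x0 - x0.mean()) ** 2) + sum(np.sum((x - x.mean()) ** 2) for x in xs)
    s2 = ss / df
    if s2 <= 0:
        raise ValueError("degenerate: zero pooled variance")

    est = np.array([x.mean() - x0.mean() for x in xs])
    se = np.sqrt(s2 * (1.0 / ns + 1.0 / n0))
    tstat = est / se
    corr = _dunnett_corr(ns, n0)
    p_adj = np.array([1.0 - _max_abs_le(abs(t), corr, df) for t in tstat])
    p_unadj = 2.0 * sstats.t.sf(np.abs(tstat), df)
    p_adj = np.clip(np.maximum(p_adj, p_unadj), 0.0, 1.0)
    return DunnettResult(comparisons=[str(g) for g in labels], estimates=est,
                         statistics=tstat, p_adjusted=p_adj,
                         p_unadjusted=p_unadj, df=df)


def dunnett_critical_value(ns, n0: int, df: int, alpha: float = 0.05) -> float:
    """Equicoordinate two-sided critical value c with
    P(max_i |T_i| <= c) = 1 − alpha for the Dunnett joint null."""
    corr = _dunnett_corr(np.asarray(ns, float), n0)
    return brentq(lambda c: _max_abs_le(c, corr, df) - (1.0 - alpha), 1.0, 10.0,
                  xtol=1e-4)


# ---------------------------------------------------------------------------
# ANOVA and group summaries
# ---------------------------------------------------------------------------

def anova_oneway(samples: list[np.ndarray]) -> float:
    """One-way fixed-effects ANOVA p-value across the given group samples."""
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    return float(sstats.f_oneway(*samples).pvalue)

def group_summary(table: pd.DataFrame, variables: list[str],
                  group_col: str = "group", control: str = "sham") -> GroupSummary:
    """Mean/SD/n per group plus one-way ANOVA and Dunnett-adjusted p per
    variable.  Missing values are dropped pairwise per variable (n reported
    per cell); empty groups are dropped with a log note; zero-variance
    variables get no ANOVA p (reason recorded in ``notes``)."""
    notes: list[str] = []
    groups = [g for g in table[group_col].dropna().unique()]
    sizes = table.groupby(group_col, sort=False).size()
    for g in list(groups):
        if sizes.get(g, 0) == 0:
            groups.remove(g)
            notes.append(f"group {g!r} empty; dropped")
            logger.info("group %r empty; dropped", g)

    rows = []
    anova_p: dict[str, float] = {}
    dunnett_p: dict[str, dict[str, float]] = {}
    for var in variables:
        samples, labels = [], []
        for g in groups:
            x = table.loc[table[group_col] == g, var].dropna().to_numpy(float)
            rows.append({"variable": var, "group": g,
                         "mean": x.mean() if x.size else np.nan,
                         "sd": x.std(ddof=1) if x.size > 1 else np.nan,
                         "n": int(x.size)})
            if x.size >= 2:
                samples.append(x)
                labels.append(g)
        pooled = np.concatenate(samples) if samples else np.array([])
        if len(samples) >= 2 and np.ptp(pooled) > 0:
            anova_p[var] = anova_oneway(samples)
        else:
            reason = ("zero variance" if pooled.size and np.ptp(pooled) == 0
                      else "fewer than 2 usable groups")
            notes.append(f"{var}: ANOVA p absent ({reason})")
        if control in labels and len(labels) >= 2 and var in anova_p:
            vals = np.concatenate(samples)
            labs = np.concatenate([[g] * s.size for g, s in zip(labels, samples)])
            try:
                res = dunnett(vals, labs, control)
                dunnett_p[var] = dict(zip(res.comparisons, res.p_adjusted))
            except ValueError as exc:
                notes.append(f"{var}: Dunnett absent ({exc})")
    return GroupSummary(table=pd.DataFrame(rows), anova_p=anova_p,
                        dunnett_p=dunnett_p, notes=notes)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def pearson(x, y) -> CorrResult:
    """Pearson product-moment correlation with a two-sided t-test p
    (n − 2 df) and the least-squares regression line of y on x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need n >= 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate: zero variance")
    r, p = sstats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return CorrResult(r=float(r), p_value=float(p), n=int(x.size),
                      slope=float(slope), intercept=float(intercept))
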