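"""Clinical quantities and cohort statistics for CP volumetry studies.

Implements the albumin quotient (Qalb) and baseline progression rate (BPR)
formulas, covariate-adjusted general-linear-model group comparisons with
family-wise-error-corrected pairwise contrasts, partial correlations by
residualisation, and one-way ANOVA / Student t / chi-square tests
reconstructed from printed (n, mean, SD) group summaries.

Conventions: sex is coded 0/1 (F/M) in design matrices; all p-values are
two-sided; the FWE default is Bonferroni over the family of pairwise group
contrasts (Holm available by flag); analyses are complete-case per
variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ParameterError

SEX_CODING = {"F": 0.0, "M": 1.0}


# --------------------------------------------------------------------------
# clinical quantities
# --------------------------------------------------------------------------

def qalb(csf_albumin_mg_l, serum_albumin_g_l):
    """CSF/serum albumin quotient in mg/g.

    CSF albumin is in mg/L and serum albumin in g/L, so the plain ratio is
    numerically on the mg/g scale used for blood-CSF-barrier permeability.
    Accepts scalars or arrays; non-positive inputs raise.
    """
    csf = np.asarray(csf_albumin_mg_l, dtype=float)
    serum = np.asarray(serum_albumin_g_l, dtype=float)
    if np.any(csf <= 0) or np.any(serum <= 0):
        raise ParameterError("albumin concentrations must be positive")
    out = csf / serum
    return float(out) if out.ndim == 0 else out


def bpr(alsfrs_r, duration_months):
    """Baseline progression rate: (48 - ALSFRS-R) / disease duration.

    Units are ALSFRS-R points lost per month. ALSFRS-R must lie in [0, 48]
    and duration must be positive.
    """
    score = np.asarray(alsfrs_r, dtype=float)
    dur = np.asarray(duration_months, dtype=float)
    if np.any((score < 0) | (score > 48)):
        raise ParameterError("ALSFRS-R must lie in [0, 48]")
    if np.any(dur <= 0):
        raise ParameterError("disease duration must be positive")
    out = (48.0 - score) / dur
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# summary-statistic tests (reconstruction from printed n / mean / SD)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSummary:
    """(n, mean, sd) of one variable in one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ParameterError(f"group summary needs n >= 2, got n={self.n}")
        if self.sd < 0:
            raise ParameterError(f"sd must be >= 0, got {self.sd}")


def anova_from_summary(groups) -> tuple[float, int, int, float]:
    """One-way ANOVA (F, df1, df2, p) from per-group (n, mean, sd).

    Between-groups SS comes from the group means about the grand mean;
    within-groups SS is sum of (n_i - 1) * sd_i^2. Identical to raw-data
    one-way ANOVA whenever raw data match the summaries exactly.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ParameterError("ANOVA needs at least two groups")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups], dtype=float)
    s = np.array([g.sd for g in groups], dtype=float)
    ntot = n.sum()
    grand = float(np.sum(n * m) / ntot)
    ss_between = float(np.sum(n * (m - grand) ** 2))
    ss_within = float(np.sum((n - 1.0) * s * s))
    df1 = len(groups) - 1
    df2 = int(ntot) - len(groups)
    if df2 <= 0:
        raise ParameterError("no within-group degrees of freedom")
    if ss_within == 0.0:
        f = 0.0 if ss_between == 0.0 else np.inf
    else:
        f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def ttest_from_summary(
    a: GroupSummary, b: GroupSummary, pooled: bool = True
) -> tuple[float, float, float]:
    """Two-sample t (t, df, p) from (n, mean, sd); pooled Student t by
    default, Welch with ``pooled=False``."""
    if pooled:
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (
            va**2 / (a.n - 1) + vb**2 / (b.n - 1)
        )
    if se == 0.0:
        if a.mean == b.mean:
            return 0.0, float(df), 1.0
        raise ParameterError("zero standard error with unequal means")
    t = (a.mean - b.mean) / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), float(df), p


def chisq_contingency(table) -> tuple[float, int, float]:
    """Pearson chi-square (chi2, df, p) without continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ParameterError("contingency table must be 2-D")
    if np.any(table < 0):
        raise ParameterError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ParameterError("contingency table has a zero margin")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


# --------------------------------------------------------------------------
# partial correlation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PartialCorrResult:
    r: float
    df: int
    p: float
    n: int
    covariates: tuple[str, ...]


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def partial_correlation(x, y, covariates=None, covariate_names=()) -> PartialCorrResult:
    """Pearson correlation of x and y after removing covariate effects.

    Both variables are residualised on the covariates plus an intercept by
    least squares; ``r`` is the Pearson correlation of the residuals and
    the two-sided p comes from t = r * sqrt(df / (1 - r^2)) with
    df = n - 2 - (number of covariates).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ParameterError("x and y must have equal length")
    n = x.size
    if covariates is None:
        c = np.empty((n, 0))
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
    k = c.shape[1]
    if n <= k + 3:
        raise ParameterError(f"need n > covariates + 3, got n={n}, k={k}")
    design = np.column_stack([np.ones(n), c])
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    sx, sy = float(np.std(rx)), float(np.std(ry))
    # relative guard: residuals that are numerically zero (perfect
    # collinearity with the covariates) leave the correlation undefined
    if sx <= 1e-10 * max(1.0, float(np.std(x))) or \
       sy <= 1e-10 * max(1.0, float(np.std(y))):
        raise ParameterError("zero-variance residuals; partial correlation "
                             "undefined")
    r = float(np.dot(rx, ry) / (n * sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), df))
    names = tuple(covariate_names) if covariate_names else tuple(
        f"c{i}" for i in range(k)
    )
    return PartialCorrResult(r=r, df=df, p=p, n=n, covariates=names)


# --------------------------------------------------------------------------
# covariate-adjusted GLM group comparison
# --------------------------------------------------------------------------

@dataclass
class Contrast:
    pair: tuple[str, str]
    estimate: float
    t: float
    p_raw: float
    p_adjusted: float


@dataclass
class GLMResult:
    coefficients: dict
    f_omnibus: float
    df_num: int
    df_den: int
    p_omnibus: float
    contrasts: list
    n: int
    fwe_method: str


def _adjust_fwe(p_raw: np.ndarray, method: str) -> np.ndarray:
    m = len(p_raw)
    if method == "bonferroni":
        return np.minimum(1.0, m * p_raw)
    if method == "holm":
        order = np.argsort(p_raw)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_raw[idx])
            adj[idx] = min(1.0, running)
        return adj
    raise ParameterError(f"unknown FWE method {method!r}")


def glm_group_comparison(
    cohort: pd.DataFrame,
    outcome: str = "cp_volume_mm3",
    group_col: str = "group",
    covariates: tuple[str, ...] = ("age", "sex", "tiv_mm3"),
    fwe: str = "bonferroni",
) -> GLMResult:
    """Least-squares GLM of ``outcome`` on group dummies plus covariates.

    The omnibus test for the group factor is the nested-model F comparing
    the full model against the covariates-only model. All pairwise group
    contrasts are tested on the full model and FWE-adjusted across the
    pairwise family. Rows with missing values in any used column are
    dropped (complete-case).
    """
    cols = [outcome, group_col, *covariates]
    df = cohort[cols].dropna().copy()
    groups = sorted(df[group_col].astype(str).unique())
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    if "sex" in covariates:
        df["sex"] = df["sex"].map(lambda v: SEX_CODING.get(v, v)).astype(float)

    y = df[outcome].to_numpy(dtype=float)
    n = len(df)
    dummies = np.column_stack(
        [(df[group_col] == g).to_numpy(dtype=float) for g in groups[1:]]
    )
    covs = df[list(covariates)].to_numpy(dtype=float)
    x_full = np.column_stack([np.ones(n), dummies, covs])
    if n <= x_full.shape[1]:
        raise ParameterError("fewer subjects than model parameters")
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ParameterError("design matrix is rank deficient")

    names = (
        ["intercept"]
        + [f"group[{g}]" for g in groups[1:]]
        + list(covariates)
    )
    full = sm.OLS(y, x_full).fit()
    reduced = sm.OLS(y, np.column_stack([np.ones(n), covs])).fit()

    q = len(groups) - 1
    df_den = n - x_full.shape[1]
    rss_f, rss_r = float(full.ssr), float(reduced.ssr)
    if rss_f == 0.0:
        f_stat = 0.0 if np.isclose(rss_r, rss_f) else np.inf
    else:
        f_stat = ((rss_r - rss_f) / q) / (rss_f / df_den)
    f_stat = max(f_stat, 0.0)
    p_omni = float(sps.f.sf(f_stat, q, df_den))

    # pairwise contrasts on the full model
    pairs = [(groups[i], groups[j]) for i in range(len(groups))
             for j in range(i + 1, len(groups))]
    p_raw, rows = [], []
    for g1, g2 in pairs:
        contrast = np.zeros(x_full.shape[1])
        for g, sign in ((g1, 1.0), (g2, -1.0)):
            if g != groups[0]:
                contrast[1 + groups[1:].index(g)] = sign
        tt = full.t_test(contrast)
        rows.append((g1, g2, float(np.squeeze(tt.effect)),
                     float(np.squeeze(tt.tvalue))))
        p_raw.append(float(np.squeeze(tt.pvalue)))
    p_adj = _adjust_fwe(np.array(p_raw), fwe)
    contrasts = [
        Contrast(pair=(g1, g2), estimate=est, t=t, p_raw=pr, p_adjusted=pa)
        for (g1, g2, est, t), pr, pa in zip(rows, p_raw, p_adj)
    ]

    return GLMResult(
        coefficients=dict(zip(names, full.params)),
        f_omnibus=float(f_stat),
        df_num=q,
        df_den=df_den,
        p_omnibus=p_omni,
        contrasts=contrasts,
        n=n,
        fwe_method=fwe,
    )
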