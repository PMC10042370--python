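"""Cohort statistics: three-way mixed MANOVA and companions.

The design is 2 (condition: threat / reference, within subjects) x 2 (group:
LBP / back-healthy) x 2 (EBS: low / high), with two predefined dependent-
variable sets — the variability/stability set {MeanSD x 3, CyclSD, LDE} and
the amplitude/velocity set {amplitude x 3, velocity}.

The mixed model is decomposed the standard way: within-subject effects are
multivariate tests on the per-participant condition differences regressed on
the between-subjects design (intercept = condition main effect, group column =
condition x group interaction, ...), and between-subject effects are tests on
the per-participant condition means.  Effects are tested with Wilks' Lambda;
every effect in a 2x2x2 design has one hypothesis degree of freedom, for which
the F transform of Lambda is exact:

    F = (1 - L) / L * (nu_e - p + 1) / p,   df = (p, nu_e - p + 1)

with p dependent variables and error df nu_e = N - 4.  For N = 60 this gives
the design dfs (5, 52) and (4, 53).  Type III sums of squares via effect
coding accommodate the (possibly) unbalanced EBS cells.  Univariate follow-up
ANOVAs report partial eta squared = SS_effect / (SS_effect + SS_error), which
for 1-df effects equals F / (F + df_error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import CONDITION_REFERENCE, CONDITION_THREAT, GROUP_LBP

__all__ = [
    "StatsError",
    "ManovaResult",
    "UnivariateEffect",
    "VARIABILITY_DVS",
    "AMPLITUDE_DVS",
    "SKEWED_COLUMNS",
    "ebs_split",
    "transform_skewed",
    "mixed_manova",
    "univariate_followup",
    "partial_eta_squared",
    "nonparametric_suite",
]

#: the two predefined dependent-variable sets
VARIABILITY_DVS = ("meansd_fe", "meansd_ar", "meansd_lb", "cyclsd", "lde")
AMPLITUDE_DVS = ("amplitude_fe", "amplitude_ar", "amplitude_lb", "velocity")

#: metrics that are skewed and log transformed before testing (LDE is not)
SKEWED_COLUMNS = (
    "meansd_fe", "meansd_ar", "meansd_lb", "cyclsd",
    "amplitude_fe", "amplitude_ar", "amplitude_lb", "velocity",
)

EBS_SPLIT_THRESHOLD = 3  # <= 3 low, >= 4 high


class StatsError(ValueError):
    """Statistical stage failed."""


@dataclass
class UnivariateEffect:
    dv: str
    effect: str
    F: float
    p: float
    partial_eta_sq: float
    df_num: int
    df_den: int


@dataclass
class ManovaResult:
    effect: str
    wilks_lambda: float
    F: float
    df_num: int
    df_den: int
    p: float
    univariate: list[UnivariateEffect] = field(default_factory=list)


def ebs_split(ebs_value) -> str:
    """Dichotomize an Expected Back Strain score: <= 3 'low', >= 4 'high'.

    Classification uses the score assessed before the first (threat) trial.
    """
    arr = np.asarray(ebs_value)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.asarray(arr, dtype=float) == np.asarray(arr, dtype=float).astype(int)):
            raise StatsError("EBS scores must be integers")
        arr = arr.astype(int)
    if np.any((arr < 0) | (arr > 10)):
        raise StatsError(f"EBS score out of range 0-10: {ebs_value}")
    out = np.where(arr <= EBS_SPLIT_THRESHOLD, "low", "high")
    return out.item() if out.ndim == 0 else out


def transform_skewed(table: pd.DataFrame, columns=SKEWED_COLUMNS) -> pd.DataFrame:
    """Natural-log transform the skewed metric columns; LDE is left as is."""
    out = table.copy()
    for col in columns:
        if col not in out.columns:
            continue
        vals = out[col].to_numpy(dtype=float)
        bad = np.flatnonzero(~(vals > 0))
        if bad.size:
            raise StatsError(
                f"column {col!r} has non-positive value at row {out.index[bad[0]]}; "
                "cannot log transform"
            )
        out[col] = np.log(vals)
    return out


def _participant_frame(table: pd.DataFrame, dvs) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Pivot the long table to per-participant difference and mean scores."""
    required = {"participant", "condition", "group", "ebs_threat"}
    missing = required - set(table.columns)
    if missing:
        raise StatsError(f"cohort table is missing columns: {sorted(missing)}")
    wide = {}
    for cond in (CONDITION_THREAT, CONDITION_REFERENCE):
        sub = table[table["condition"] == cond].set_index("participant")
        wide[cond] = sub
    incomplete = sorted(
        set(wide[CONDITION_THREAT].index).symmetric_difference(wide[CONDITION_REFERENCE].index)
    )
    if incomplete:
        raise StatsError(f"participants missing a condition: {incomplete}")
    idx = wide[CONDITION_THREAT].index.sort_values()
    dup = idx[idx.duplicated()]
    if len(dup):
        raise StatsError(f"duplicate rows for participants: {sorted(set(dup))}")
    t = wide[CONDITION_THREAT].loc[idx, list(dvs)].to_numpy(dtype=float)
    r = wide[CONDITION_REFERENCE].loc[idx, list(dvs)].to_numpy(dtype=float)
    meta = wide[CONDITION_THREAT].loc[idx, ["group", "ebs_threat"]]
    return meta, t - r, (t + r) / 2.0


def _design_matrix(meta: pd.DataFrame) -> np.ndarray:
    """Effect-coded between-subjects design: intercept, group, EBS, group x EBS."""
    g = np.where(meta["group"].to_numpy() == GROUP_LBP, 1.0, -1.0)
    ebs_cat = ebs_split(meta["ebs_threat"].to_numpy())
    e = np.where(ebs_cat == "high", 1.0, -1.0)
    return np.column_stack([np.ones(len(meta)), g, e, g * e])


def _wilks_test(Y: np.ndarray, X: np.ndarray, col: int) -> tuple[float, float, int, int, float, float, float]:
    """Wilks' Lambda exact test of one effect-coded column (1 hypothesis df).

    Returns (Lambda, F, df_num, df_den, p, SS_effect, SS_error) where the SS
    are the univariate quantities when Y has one column.
    """
    n, q = X.shape
    p = Y.shape[1]
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    E = resid.T @ resid
    nu_e = n - q
    if nu_e - p + 1 <= 0:
        raise StatsError(f"not enough participants ({n}) for {p} dependent variables")
    L = np.zeros((1, q))
    L[0, col] = 1.0
    lb = L @ beta
    H = lb.T @ np.linalg.inv(L @ XtX_inv @ L.T) @ lb
    det_E = np.linalg.det(E)
    det_T = np.linalg.det(E + H)
    if det_E <= 0 or det_T <= 0:
        raise StatsError("singular dependent-variable covariance")
    lam = det_E / det_T
    df_num = p
    df_den = nu_e - p + 1
    F = (1 - lam) / lam * df_den / df_num
    pval = float(sps.f.sf(F, df_num, df_den))
    return float(lam), float(F), df_num, df_den, pval, float(H[0, 0]), float(E[0, 0])


_WITHIN_EFFECTS = [
    ("threat", 0),
    ("threat x group", 1),
    ("threat x EBS", 2),
    ("threat x group x EBS", 3),
]
_BETWEEN_EFFECTS = [
    ("group", 1),
    ("EBS", 2),
    ("group x EBS", 3),
]


def mixed_manova(table: pd.DataFrame, dvs=VARIABILITY_DVS) -> list[ManovaResult]:
    """Three-way mixed MANOVA of the given dependent-variable set.

    ``table`` is the long cohort table (one row per participant x condition)
    with metrics already log transformed where applicable.  Returns one
    :class:`ManovaResult` per within- and between-subject effect.
    """
    meta, D, M = _participant_frame(table, dvs)
    X = _design_matrix(meta)
    results = []
    for scores, effects in ((D, _WITHIN_EFFECTS), (M, _BETWEEN_EFFECTS)):
        for name, col in effects:
            lam, F, dfn, dfd, pval, _, _ = _wilks_test(scores, X, col)
            results.append(ManovaResult(
                effect=name, wilks_lambda=lam, F=F, df_num=dfn, df_den=dfd, p=pval,
            ))
    return results


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error <= 0:
        raise StatsError("sums of squares must be positive")
    return ss_effect / (ss_effect + ss_error)


def univariate_followup(table: pd.DataFrame, dv: str) -> list[UnivariateEffect]:
    """Mixed ANOVA for one dependent variable, with partial eta squared.

    Same decomposition as the MANOVA with a single column; for every 1-df
    effect, partial eta squared equals F / (F + df_error).
    """
    meta, D, M = _participant_frame(table, [dv])
    X = _design_matrix(meta)
    out = []
    for scores, effects in ((D, _WITHIN_EFFECTS), (M, _BETWEEN_EFFECTS)):
        for name, col in effects:
            _, F, dfn, dfd, pval, ss_h, ss_e = _wilks_test(scores, X, col)
            out.append(UnivariateEffect(
                dv=dv, effect=name, F=F, p=pval,
                partial_eta_sq=partial_eta_squared(ss_h, ss_e),
                df_num=dfn, df_den=dfd,
            ))
    return out


def nonparametric_suite(table: pd.DataFrame) -> dict:
    """Descriptive group comparisons on the participant-level covariates.

    Mann-Whitney U between groups on the ordinal scores (EBS both conditions,
    PCS, PASS), Wilcoxon signed-rank on EBS threat vs reference, independent
    t-tests on height and weight, and the Spearman correlation between the
    two EBS assessments.
    """
    first = table.drop_duplicates("participant").set_index("participant")
    if first.empty:
        raise StatsError("empty cohort table")
    lbp = first[first["group"] == GROUP_LBP]
    ctl = first[first["group"] != GROUP_LBP]
    if lbp.empty or ctl.empty:
        raise StatsError("both groups are required")
    out: dict[str, dict] = {}
    for col in ("ebs_threat", "ebs_reference", "pcs", "pass"):
        if col not in first.columns:
            continue
        u, p = sps.mannwhitneyu(lbp[col], ctl[col], alternative="two-sided")
        out[f"mannwhitney_{col}"] = {"U": float(u), "p": float(p)}
    for col in ("height", "weight"):
        if col not in first.columns:
            continue
        t, p = sps.ttest_ind(lbp[col], ctl[col])
        out[f"ttest_{col}"] = {"t": float(t), "p": float(p)}
    d = first["ebs_threat"].to_numpy(dtype=float) - first["ebs_reference"].to_numpy(dtype=float)
    w, p = sps.wilcoxon(
        first["ebs_threat"], first["ebs_reference"],
        zero_method="zsplit", method="approx", correction=False,
    )
    out["wilcoxon_ebs"] = {"W": float(w), "p": float(p), "mean_difference": float(d.mean())}
    rho, p = sps.spearmanr(first["ebs_threat"], first["ebs_reference"])
    out["spearman_ebs"] = {"rho": float(rho), "p": float(p)}
    return out
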