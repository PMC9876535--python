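"""Group-level statistics for pre/post two-group network measures.

The analysis chain mirrors a task-aftereffect design: per-epoch network
measures are averaged to one value per subject × timepoint × band × measure;
outliers are screened per group with an iterative Grubbs test; pre-task
group differences use two-sided permutation tests with Benjamini–Hochberg
FDR across frequency bands; pre→post change is modelled with a linear mixed
model (timepoint, group, their interaction, age/gender/education covariates,
subject random intercept), followed up per group where the timepoint or
interaction effect survives FDR; and vertex-wise post/pre eccentricity
ratios are compared between groups with a max-t permutation test that
controls the family-wise error across channels.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

__all__ = [
    "LmmResult",
    "VertexStatMap",
    "average_over_epochs",
    "grubbs_iterative",
    "permutation_group_test",
    "fdr_bh",
    "fit_lmm",
    "per_group_lmm",
    "eccentricity_ratio",
    "maxT_permutation",
]


def average_over_epochs(values) -> float:
    """Arithmetic mean of one subject/timepoint/band's per-epoch measures."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot average an empty set of epoch values")
    return float(x.mean())


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value via the Student-t quantile formula."""
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_iterative(values, alpha: float = 0.05) -> list[int]:
    """Indices of outliers found by repeated two-sided Grubbs tests.

    The most extreme value is tested with G = max|x − x̄|/s against the
    critical value at level ``alpha`` and removed if significant; this
    repeats until nothing is flagged or fewer than 3 values remain.  A
    zero-variance sample yields no outliers.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("Grubbs screening needs a 1-d sample of size >= 3")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    idx = np.arange(x.size)
    flagged: list[int] = []
    while x.size >= 3:
        s = x.std(ddof=1)
        if s <= 0:
            break
        dev = np.abs(x - x.mean())
        k = int(np.argmax(dev))
        if dev[k] / s > grubbs_critical(x.size, alpha):
            flagged.append(int(idx[k]))
            x = np.delete(x, k)
            idx = np.delete(idx, k)
        else:
            break
    return flagged


def permutation_group_test(
    group_a,
    group_b,
    n_perm: int = 10_000,
    seed: int | None = None,
    exact: bool = False,
) -> float:
    """Two-sided permutation test on the difference of group means.

    Monte-Carlo p-values carry the +1 small-sample correction,
    ``p = (1 + #{|stat*| >= |stat|}) / (n_perm + 1)``.  With ``exact=True``
    all label assignments are enumerated instead and the p-value is the
    plain exceedance fraction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    n_a = a.size
    observed = abs(a.mean() - b.mean())
    tol = 1e-12 * max(1.0, observed)
    if exact:
        total = math.comb(pooled.size, n_a)
        if total > 2_000_000:
            raise ValueError("exact enumeration infeasible; use Monte Carlo")
        count = 0
        for combo in itertools.combinations(range(pooled.size), n_a):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(combo)] = True
            stat = abs(pooled[mask].mean() - pooled[~mask].mean())
            if stat >= observed - tol:
                count += 1
        return count / total
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:n_a].mean() - perm[n_a:].mean()) >= observed - tol:
            count += 1
    return (1 + count) / (n_perm + 1)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class LmmResult:
    """Fixed effects of a mixed model plus variance components."""

    estimates: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    random_intercept_var: float
    residual_var: float
    n_subjects: int
    n_obs: int
    converged: bool
    singular: bool


def _code_design(table: pd.DataFrame, covariates: bool) -> pd.DataFrame:
    df = table.copy()
    bad_tp = set(df["timepoint"]) - {"pre", "post"}
    if bad_tp:
        raise ValueError(f"unknown timepoint labels: {sorted(bad_tp)}")
    bad_grp = set(df["group"]) - {"control", "MCI"}
    if bad_grp:
        raise ValueError(f"unknown group labels: {sorted(bad_grp)}")
    df["tp"] = (df["timepoint"] == "post").astype(float)
    df["grp"] = (df["group"] == "MCI").astype(float)
    if covariates:
        bad_g = set(df["gender"]) - {"female", "male"}
        if bad_g:
            raise ValueError(f"unknown gender labels: {sorted(bad_g)}")
        df["male"] = (df["gender"] == "male").astype(float)
        df["age_c"] = df["age"] - df["age"].mean()
        df["edu_c"] = df["education"] - df["education"].mean()
    return df


def _fit_mixed(df: pd.DataFrame, formula: str, random_slope: bool = False) -> LmmResult:
    if df["value"].nunique() <= 1:
        raise ValueError("degenerate data: the response is constant")
    import warnings

    re_formula = "~tp" if random_slope else None
    model = smf.mixedlm(formula, df, groups=df["subject"], re_formula=re_formula)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)  # singular RE covariance; we log it
        try:
            result = model.fit(reml=True)
        except np.linalg.LinAlgError as err:  # e.g. a constant covariate column
            raise ValueError(f"singular mixed-model design: {err}") from err
    re_var = float(np.asarray(result.cov_re)[0, 0])
    singular = bool(re_var < 1e-10 * max(result.scale, 1e-300)) or not result.converged
    if singular:
        logger.warning("mixed model fit is singular or did not converge (%s)", formula)
    names = [n for n in result.params.index if n != "Group Var"]
    return LmmResult(
        estimates={n: float(result.params[n]) for n in names},
        std_errors={n: float(result.bse[n]) for n in names},
        p_values={n: float(result.pvalues[n]) for n in names},
        random_intercept_var=re_var,
        residual_var=float(result.scale),
        n_subjects=int(df["subject"].nunique()),
        n_obs=int(len(df)),
        converged=bool(result.converged),
        singular=singular,
    )


def _require_both_timepoints(df: pd.DataFrame) -> pd.DataFrame:
    counts = df.groupby("subject")["timepoint"].nunique()
    complete = counts[counts == 2].index
    dropped = sorted(set(df["subject"]) - set(complete))
    if dropped:
        logger.info("dropping subjects without both timepoints: %s", dropped)
    return df[df["subject"].isin(complete)]


def fit_lmm(
    table: pd.DataFrame, covariates: bool = True, random_slope: bool = False
) -> LmmResult:
    """Mixed model for one measure × band over the whole cohort.

    Fits ``value ~ timepoint + group + timepoint:group (+ age + gender +
    education)`` with a subject random intercept (optionally also a random
    timepoint slope per subject).  Timepoint is coded pre=0/post=1 and group
    control=0/MCI=1, so the interaction coefficient is the MCI-specific
    pre→post increment; age and education are mean-centred and gender coded
    female=0/male=1.  Inference is by Wald tests on the fixed effects.
    """
    df = _require_both_timepoints(_code_design(table, covariates))
    if df.groupby("group")["subject"].nunique().min() < 2:
        raise ValueError("need at least 2 subjects per group")
    formula = "value ~ tp * grp"
    if covariates:
        formula += " + age_c + male + edu_c"
    return _fit_mixed(df, formula, random_slope=random_slope)


def per_group_lmm(
    table: pd.DataFrame,
    group: str,
    covariates: bool = True,
    random_slope: bool = False,
) -> LmmResult:
    """Follow-up mixed model within one group (timepoint effect only)."""
    df = _code_design(table, covariates)
    df = _require_both_timepoints(df[df["group"] == group])
    if df["subject"].nunique() < 2:
        raise ValueError(f"need at least 2 subjects in group {group!r}")
    formula = "value ~ tp"
    if covariates:
        formula += " + age_c + male + edu_c"
    return _fit_mixed(df, formula, random_slope=random_slope)


def eccentricity_ratio(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    """Per-vertex post/pre eccentricity ratios (< 1: vertex became more central)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post eccentricities must have the same shape")
    if np.any(pre <= 0):
        raise ValueError("pre-task eccentricities must be positive")
    return post / pre


@dataclass
class VertexStatMap:
    """Per-vertex group-difference t statistics and FWE-corrected p-values."""

    t_values: np.ndarray
    p_fwe: np.ndarray
    channels: tuple[str, ...] | None = None


def _pooled_t(x: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Two-sample pooled-variance t per column for one label assignment."""
    n_a = int(mask_a.sum())
    n_b = mask_a.size - n_a
    a, b = x[mask_a], x[~mask_a]
    mean_diff = a.mean(axis=0) - b.mean(axis=0)
    ss = (n_a - 1) * a.var(axis=0, ddof=1) + (n_b - 1) * b.var(axis=0, ddof=1)
    sp2 = ss / (n_a + n_b - 2)
    denom = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, mean_diff / denom, 0.0)
    return t


def maxT_permutation(
    ratios: np.ndarray,
    groups,
    n_perm: int = 10_000,
    seed: int | None = None,
    channels: tuple[str, ...] | None = None,
) -> VertexStatMap:
    """Max-t permutation test across vertices with FWE control.

    ``ratios`` is subjects × vertices; ``groups`` the per-subject labels (two
    levels).  Per vertex the observed two-sample pooled-variance t is
    referred to the permutation distribution of the maximum of |t| over
    vertices, giving family-wise-error corrected p-values
    ``p_v = (1 + #{max-null >= |t_v|}) / (n_perm + 1)``.
    """
    x = np.asarray(ratios, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratios must be subjects × vertices")
    labels = np.asarray(groups)
    if labels.shape[0] != x.shape[0]:
        raise ValueError("groups length must match the number of subjects")
    levels = np.unique(labels)
    if levels.size != 2:
        raise ValueError("exactly two group levels required")
    mask_a = labels == levels[0]
    if mask_a.sum() < 2 or (~mask_a).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")

    t_obs = _pooled_t(x, mask_a)
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        max_null[b] = np.max(np.abs(_pooled_t(x, rng.permutation(mask_a))))
    abs_t = np.abs(t_obs)
    p_fwe = (1 + (max_null[None, :] >= abs_t[:, None]).sum(axis=1)) / (n_perm + 1)
    return VertexStatMap(t_values=t_obs, p_fwe=p_fwe, channels=channels)
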