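"""Moderated differential statistics with randomization FDR, plus the
supporting tests used across the omics layers.

The central statistic is the SAM-style moderated two-sample t

    d = (mean_a - mean_b) / (SE_pooled + s0)

where ``SE_pooled`` is the usual equal-variance pooled standard error and
``s0`` (default 0.1) is an additive constant that damps the significance of
features whose variance is small by chance. Significance is assessed by a
randomization procedure: group labels are permuted (jointly across features,
preserving the feature correlation structure), the null distribution of |d|
is accumulated, and for a threshold t the estimated FDR is

    FDR(t) = mean over permutations of #{|d*| >= t} / #{|d| >= t}.

The significant set is the largest set with estimated FDR at or below the
target (default 0.05 with 250 randomizations).

Also provided: Perseus-style downshifted-normal imputation for
missing-not-at-random intensities, a many-to-one Dunnett-adjusted one-way
ANOVA, Benjamini-Hochberg adjustment, and Fisher-exact over-representation
analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DiffTestParams",
    "ImputeParams",
    "VolcanoResult",
    "s0_statistic",
    "permutation_fdr",
    "impute_downshift",
    "anova_dunnett",
    "bh_adjust",
    "fisher_ora",
]


@dataclass(frozen=True)
class DiffTestParams:
    """Parameters of the moderated test with randomization FDR."""

    s0: float = 0.1
    n_perm: int = 250
    fdr_target: float = 0.05
    min_per_group: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0 < self.fdr_target < 1):
            raise ValueError("fdr_target must be in (0, 1)")


@dataclass(frozen=True)
class ImputeParams:
    """Downshifted-normal imputation parameters (Perseus convention).

    Missing values in sample j are drawn from
    Normal(mean_j - downshift * sd_j, (width * sd_j)^2) where mean_j/sd_j
    are computed from the sample's present values. Defaults width=0.3,
    downshift=1.8.
    """

    width: float = 0.3
    downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")


def _moderated_d(
    a: np.ndarray, b: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized moderated statistic over a feature x replicate block.

    ``a``/``b`` are 2-D (features x replicates) with NaN for missing.
    Returns (d, log2_fc, testable) arrays; untestable rows (fewer than 2
    present values in a group) get NaN d.
    """
    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)
    testable = (na >= 2) & (nb >= 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(a, axis=1)
        mb = np.nanmean(b, axis=1)
        va = np.nanvar(a, axis=1, ddof=1)
        vb = np.nanvar(b, axis=1, ddof=1)
    fc = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        d = fc / (se + s0)
    d = np.where(testable, d, np.nan)
    return d, fc, testable


def s0_statistic(
    x_a: Sequence[float],
    x_b: Sequence[float],
    s0: float = 0.1,
    min_per_group: int = 3,
) -> tuple[float, float]:
    """Moderated two-sample statistic for one feature.

    Returns ``(d, log2_fc)`` with ``log2_fc = mean(x_a) - mean(x_b)`` and
    ``d = log2_fc / (SE_pooled + s0)``. With ``s0 = 0`` this is exactly the
    pooled two-sample Student t. If either group has fewer than
    ``min_per_group`` present values the feature is untestable and
    ``d`` is NaN (the fold change is still reported when computable).
    """
    a = np.asarray(x_a, dtype=float)
    b = np.asarray(x_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < min_per_group or len(b) < min_per_group:
        fc = float(np.mean(a) - np.mean(b)) if len(a) and len(b) else math.nan
        return math.nan, fc
    d, fc, _ = _moderated_d(a[None, :], b[None, :], s0)
    return float(d[0]), float(fc[0])


@dataclass
class VolcanoResult:
    """Per-feature differential results from the randomization test."""

    table: pd.DataFrame  # columns: log2_fc, d, q_value, significant, testable
    params: DiffTestParams

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def permutation_fdr(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    params: DiffTestParams = DiffTestParams(),
) -> VolcanoResult:
    """Two-group moderated test with permutation-estimated FDR.

    ``matrix`` is a feature x sample log2 DataFrame. Group labels are
    permuted jointly across all features per randomization. For each
    feature, the q-value is the smallest estimated FDR over all |d|
    thresholds that admit it; a feature is significant iff its q-value is
    at or below ``params.fdr_target``. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    cols = [*group_a, *group_b]
    x = matrix[cols].to_numpy(dtype=float)
    na = len(group_a)
    d_obs, fc, _ = _moderated_d(x[:, :na], x[:, na:], params.s0)
    counts_a = np.sum(~np.isnan(x[:, :na]), axis=1)
    counts_b = np.sum(~np.isnan(x[:, na:]), axis=1)
    testable = (counts_a >= params.min_per_group) & (counts_b >= params.min_per_group)
    d_obs = np.where(testable, d_obs, np.nan)

    n_total = len(cols)
    n_distinct = math.comb(n_total, na)
    if params.n_perm > n_distinct:
        warnings.warn(
            f"n_perm={params.n_perm} exceeds the {n_distinct} distinct group-label "
            "assignments; sampling with replacement",
            stacklevel=2,
        )

    abs_obs = np.abs(d_obs)
    finite = np.isfinite(abs_obs)
    perm_pool = np.empty((params.n_perm, x.shape[0]))
    for p in range(params.n_perm):
        perm = rng.permutation(n_total)
        xp = x[:, perm]
        d_p, _, _ = _moderated_d(xp[:, :na], xp[:, na:], params.s0)
        perm_pool[p] = np.abs(d_p)
    perm_flat = np.sort(perm_pool[np.isfinite(perm_pool)])

    # FDR(t) at each observed |d| threshold, then q = min FDR over
    # thresholds admitting the feature (suffix minimum in sorted order).
    obs_sorted = np.sort(abs_obs[finite])  # ascending
    thresholds = obs_sorted[::-1]  # descending
    n_obs_ge = np.arange(1, len(thresholds) + 1)
    n_perm_ge = len(perm_flat) - np.searchsorted(perm_flat, thresholds, side="left")
    mean_null = n_perm_ge / params.n_perm
    fdr_at = np.minimum(mean_null / n_obs_ge, 1.0)
    q_sorted = np.minimum.accumulate(fdr_at[::-1])[::-1]  # suffix min, descending order

    q = np.full(x.shape[0], np.nan)
    if len(thresholds):
        # map each finite |d| to its rank among descending thresholds
        ranks = len(obs_sorted) - np.searchsorted(obs_sorted, abs_obs[finite], side="left") - 1
        q[finite] = q_sorted[np.clip(ranks, 0, len(q_sorted) - 1)]

    significant = np.where(np.isnan(q), False, q <= params.fdr_target)
    table = pd.DataFrame(
        {
            "log2_fc": fc,
            "d": d_obs,
            "q_value": q,
            "significant": significant,
            "testable": testable,
        },
        index=matrix.index,
    )
    return VolcanoResult(table=table, params=params)


def impute_downshift(
    matrix: pd.DataFrame, params: ImputeParams = ImputeParams()
) -> pd.DataFrame:
    """Replace missing values by draws from a downshifted normal per sample.

    Present values are untouched. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    out = matrix.copy()
    empties = [c for c in out.columns if out[c].notna().sum() == 0]
    if empties:
        raise ValueError(f"cannot impute samples with no present values: {empties}")
    for col in out.columns:
        vals = out[col]
        miss = vals.isna()
        if not miss.any():
            continue
        mu = vals.mean(skipna=True)
        sd = vals.std(skipna=True, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            sd = 0.0
        draws = rng.normal(mu - params.downshift * sd, params.width * sd if sd > 0 else 0.0,
                           size=int(miss.sum()))
        out.loc[miss, col] = draws
    return out


def anova_dunnett(
    control: Sequence[float],
    treatments: Sequence[Sequence[float]],
    seed: int = 0,
) -> np.ndarray:
    """Many-to-one comparisons: each treatment group against a shared control.

    Returns the Dunnett-adjusted two-sided p-value per treatment,
    P(max_i |T_i| >= |t_j|) under the joint null of the k comparisons
    sharing the control group (equicorrelated multivariate t). Probabilities
    are evaluated by scipy's randomized quadrature with a fixed seed. With
    k = 1 the adjusted p equals the unadjusted pooled two-sided t-test p.
    Degenerate input (zero variance everywhere and equal means) yields p=1.
    """
    if len(treatments) == 0:
        raise ValueError("need at least one treatment group")
    ctrl = np.asarray(control, dtype=float)
    groups = [np.asarray(t, dtype=float) for t in treatments]
    if any(len(g) < 2 for g in groups) or len(ctrl) < 2:
        raise ValueError("need >= 2 values per group")
    allv = np.concatenate([ctrl, *groups])
    if np.allclose(np.var(allv), 0):
        return np.ones(len(groups))
    res = sps.dunnett(*groups, control=ctrl, rng=np.random.default_rng(seed))
    p = np.asarray(res.pvalue, dtype=float)
    # guard against quadrature noise pushing adjusted p below the raw p
    raw = np.array(
        [sps.ttest_ind(g, ctrl, equal_var=True).pvalue for g in groups]
    )
    # pooled variance across ALL groups (Dunnett convention) differs from
    # the pairwise pooled t; only clip at k=1 where they must coincide
    if len(groups) == 1:
        p = raw
    return np.clip(p, 0.0, 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_ora(
    foreground: set[str],
    background: set[str],
    gene_sets: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Fisher-exact over-representation of a foreground within gene sets.

    For each named set the 2x2 table is (fg in set, fg not in set, bg-only
    in set, bg-only not in set); two-sided Fisher exact p, BH-adjusted
    across sets. The foreground must be a subset of the background.
    """
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    rows = []
    for name, members in gene_sets.items():
        inset = members & background
        a = len(foreground & inset)
        b = len(foreground) - a
        c = len(inset) - a
        d = len(background) - len(foreground) - c
        odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"gene_set": name, "overlap": a, "odds_ratio": odds, "p_value": p})
    out = pd.DataFrame(rows).set_index("gene_set")
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out
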