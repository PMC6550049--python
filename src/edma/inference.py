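"""Nonparametric bootstrap inference for form-difference matrices.

Two procedures, following the standard EDMA workflow:

* :func:`bootstrap_fdm_intervals` — marginal percentile confidence
  intervals for every element of the FDM. Specimens are resampled with
  replacement *within* each group (original sizes), the two mean forms
  and their ratio vector are recomputed per resample, and per-pair
  percentile bounds are taken. A distance is flagged significant when
  its interval excludes 1.0.

* :func:`test_mean_form_difference` — a bootstrap test of the null
  hypothesis that the two samples share a mean form. The test statistic
  is T = max(FDM)/min(FDM) (T = 1 iff the mean forms are proportional).
  The null distribution is built by pooling all specimens and drawing
  both pseudo-groups, at their original sizes, with replacement from the
  pool. The p-value uses the add-one estimator
  p = (1 + #{T* ≥ T_obs}) / (1 + n_boot), so it is never exactly zero.

Randomness contract (relied on by reproducibility guarantees): a single
``numpy.random.default_rng(seed)`` generator produces, in order, all
group-A resample indices as one ``integers`` call of shape
``(n_boot, n_A)``, then all group-B indices of shape ``(n_boot, n_B)``.
Chunked evaluation never touches the RNG stream, so results are
bit-identical regardless of chunk size.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import distance_rows, estimate_mean_form, pair_index_for
from .landmarks import LandmarkDataset, ValidationError

__all__ = [
    "BootstrapCIResult",
    "FormTestResult",
    "EffectClassification",
    "bootstrap_fdm_intervals",
    "test_mean_form_difference",
    "classify_fdm_effects",
    "CATEGORIES",
]

#: Effect categories in reporting order.
CATEGORIES = (
    "increase_gt10",
    "increase_5_10",
    "decrease_5_10",
    "decrease_gt10",
    "significant_lt5",
    "not_significant",
)

# bootstrap chunk size: keeps the (chunk, n, n_pairs) workspace ~tens of MB
_CHUNK = 512


@dataclass
class BootstrapCIResult:
    """Percentile bootstrap CIs for the elements of an FDM."""

    pair_index: tuple[tuple[str, str], ...]
    ratios: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    significant: np.ndarray
    n_boot: int
    confidence_level: float
    seed: int
    estimator: str
    numerator_group: str = "numerator"
    denominator_group: str = "denominator"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "landmark_i": [p[0] for p in self.pair_index],
                "landmark_j": [p[1] for p in self.pair_index],
                "ratio": self.ratios,
                "lower": self.lower,
                "upper": self.upper,
                "significant": self.significant,
            }
        )


@dataclass
class FormTestResult:
    """Bootstrap test of equality of two mean forms."""

    statistic_observed: float
    null_statistics: np.ndarray
    p_value: float
    n_boot: int
    seed: int
    estimator: str


@dataclass
class EffectClassification:
    """Fig.-1-style banding of significant FDM elements.

    Significant distances are binned by the point-estimate ratio into
    increases/decreases of 5–10% or >10% (multiplicative bands by
    default: a 5% decrease is r ≤ 1/1.05); significant distances below
    the 5% band are reported as ``significant_lt5``; non-significant
    distances are ``not_significant`` regardless of ratio.
    """

    pair_index: tuple[tuple[str, str], ...]
    categories: np.ndarray  # array of strings from CATEGORIES
    bands: tuple[float, float]
    multiplicative: bool = True

    def counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.categories == c)) for c in CATEGORIES}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "landmark_i": [p[0] for p in self.pair_index],
                "landmark_j": [p[1] for p in self.pair_index],
                "category": self.categories,
            }
        )


def _check_two_groups(group_a: LandmarkDataset, group_b: LandmarkDataset) -> None:
    if group_a.landmark_labels != group_b.landmark_labels:
        raise ValidationError("groups have different landmark labels")
    if group_a.n_specimens < 2 or group_b.n_specimens < 2:
        raise ValidationError("each group needs at least 2 specimens")


def _group_name(ds: LandmarkDataset, default: str) -> str:
    g = ds.groups()
    return g[0] if len(g) == 1 else default


def _mean_rows(rows: np.ndarray, idx: np.ndarray, estimator: str) -> np.ndarray:
    """Mean-form estimates for a block of resamples.

    rows : (n, P) per-specimen distances; idx : (B, n) resample indices.
    Returns (B, P).
    """
    sel = rows[idx]  # (B, n, P)
    if estimator == "arithmetic":
        return sel.mean(axis=1)
    mean_d = sel.mean(axis=1)
    mean_d2 = (sel ** 2).mean(axis=1)
    var_d = sel.var(axis=1, ddof=1)
    corrected = mean_d2 - var_d
    bad = corrected <= 0.0
    return np.where(bad, mean_d, np.sqrt(np.where(bad, 1.0, corrected)))


def bootstrap_fdm_intervals(
    group_a: LandmarkDataset,
    group_b: LandmarkDataset,
    n_boot: int = 100_000,
    confidence_level: float = 0.90,
    seed: int = 0,
    estimator: str = "arithmetic",
) -> BootstrapCIResult:
    """Bootstrap percentile CIs for FDM elements (group_a / group_b).

    ``group_a`` is the numerator (test group, e.g. mutant), ``group_b``
    the denominator (reference group). Specimens are drawn with
    replacement independently within each group, keeping the observed
    group sizes; 100,000 resamples by default.
    """
    _check_two_groups(group_a, group_b)
    if n_boot < 1:
        raise ValidationError("n_boot must be at least 1")
    if not 0.0 < confidence_level < 1.0:
        raise ValidationError("confidence_level must be in (0, 1)")

    rows_a = distance_rows(group_a)
    rows_b = distance_rows(group_b)
    n_a, n_b = rows_a.shape[0], rows_b.shape[0]

    mf_a = estimate_mean_form(group_a, estimator)
    mf_b = estimate_mean_form(group_b, estimator)
    point = mf_a.distances / mf_b.distances

    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, n_a, size=(n_boot, n_a))
    idx_b = rng.integers(0, n_b, size=(n_boot, n_b))

    boot = np.empty((n_boot, rows_a.shape[1]))
    for start in range(0, n_boot, _CHUNK):
        stop = min(start + _CHUNK, n_boot)
        ma = _mean_rows(rows_a, idx_a[start:stop], estimator)
        mb = _mean_rows(rows_b, idx_b[start:stop], estimator)
        boot[start:stop] = ma / mb

    alpha = 1.0 - confidence_level
    lower, upper = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0], axis=0)
    significant = (lower > 1.0) | (upper < 1.0)
    return BootstrapCIResult(
        pair_index=pair_index_for(group_a.landmark_labels),
        ratios=point,
        lower=lower,
        upper=upper,
        significant=significant,
        n_boot=n_boot,
        confidence_level=confidence_level,
        seed=seed,
        estimator=estimator,
        numerator_group=_group_name(group_a, "group_a"),
        denominator_group=_group_name(group_b, "group_b"),
    )


def _t_statistic(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    ratios = num / den
    return ratios.max(axis=-1) / ratios.min(axis=-1)


def test_mean_form_difference(
    group_a: LandmarkDataset,
    group_b: LandmarkDataset,
    n_boot: int = 10_000,
    seed: int = 0,
    estimator: str = "arithmetic",
) -> FormTestResult:
    """Bootstrap test of the null hypothesis of equal mean forms."""
    _check_two_groups(group_a, group_b)
    if n_boot < 1:
        raise ValidationError("n_boot must be at least 1")

    rows_a = distance_rows(group_a)
    rows_b = distance_rows(group_b)
    n_a, n_b = rows_a.shape[0], rows_b.shape[0]

    mf_a = estimate_mean_form(group_a, estimator)
    mf_b = estimate_mean_form(group_b, estimator)
    t_obs = float(_t_statistic(mf_a.distances, mf_b.distances))

    pool = np.concatenate([rows_a, rows_b], axis=0)
    n_pool = n_a + n_b
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, n_pool, size=(n_boot, n_a))
    idx_b = rng.integers(0, n_pool, size=(n_boot, n_b))

    t_null = np.empty(n_boot)
    for start in range(0, n_boot, _CHUNK):
        stop = min(start + _CHUNK, n_boot)
        ma = _mean_rows(pool, idx_a[start:stop], estimator)
        mb = _mean_rows(pool, idx_b[start:stop], estimator)
        t_null[start:stop] = _t_statistic(ma, mb)

    p = (1.0 + float(np.sum(t_null >= t_obs))) / (1.0 + n_boot)
    return FormTestResult(
        statistic_observed=t_obs,
        null_statistics=t_null,
        p_value=p,
        n_boot=n_boot,
        seed=seed,
        estimator=estimator,
    )


def classify_fdm_effects(
    ci: BootstrapCIResult,
    bands: tuple[float, float] = (0.05, 0.10),
    multiplicative: bool = True,
) -> EffectClassification:
    """Band significant FDM elements by relative effect size.

    With the default ``bands=(0.05, 0.10)``: significant ratios ≥ 1.10
    are ``increase_gt10``; in [1.05, 1.10) ``increase_5_10``; the
    decrease bands mirror these multiplicatively (r ≤ 1/1.10, then
    (1/1.10, 1/1.05]) or additively (r ≤ 0.90, (0.90, 0.95]) when
    ``multiplicative=False``. Significant ratios inside the innermost
    band are ``significant_lt5``; everything non-significant is
    ``not_significant``.
    """
    lo, hi = bands
    if not 0.0 < lo < hi:
        raise ValidationError("bands must satisfy 0 < lower < upper")
    up_lo, up_hi = 1.0 + lo, 1.0 + hi
    if multiplicative:
        dn_lo, dn_hi = 1.0 / (1.0 + lo), 1.0 / (1.0 + hi)
    else:
        dn_lo, dn_hi = 1.0 - lo, 1.0 - hi

    r = ci.ratios
    cats = np.full(r.shape, "not_significant", dtype=object)
    sig = ci.significant
    cats[sig] = "significant_lt5"
    cats[sig & (r >= up_hi)] = "increase_gt10"
    cats[sig & (r >= up_lo) & (r < up_hi)] = "increase_5_10"
    cats[sig & (r <= dn_hi)] = "decrease_gt10"
    cats[sig & (r <= dn_lo) & (r > dn_hi)] = "decrease_5_10"
    return EffectClassification(
        pair_index=ci.pair_index,
        categories=np.asarray(cats, dtype=object),
        bands=(float(lo), float(hi)),
        multiplicative=multiplicative,
    )
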