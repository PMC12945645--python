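"""Cohort-level statistics and the SCD-referenced display transform.

Kruskal-Wallis across the six groups for demographics/MMSE, Welch or
Mann-Whitney for pairwise ROI comparisons (Mann-Whitney when a Shapiro-Wilk
screen rejects normality in either sample), Pearson correlations between
ROI features and MMSE with Bonferroni-Holm step-down correction, and the
bar-plot scaling that re-expresses group values relative to the SCD mean in
units of the SCD standard error.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, InvalidParameterError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupComparisonResult:
    statistic: float
    p: float
    test: str
    group_labels: tuple[str, ...]
    n_per_group: tuple[int, ...]

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise InvalidParameterError(f"p must be in [0, 1], got {self.p}")


@dataclass(frozen=True)
class CorrelationResult:
    """One ROI-feature-vs-MMSE correlation inside a Holm-corrected family."""

    name: str
    r: float
    p: float
    holm_significant: bool
    n: int


def kruskal_wallis(groups, labels=None) -> GroupComparisonResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p on k-1 df.

    All-identical data take the degenerate H = 0, p = 1 path instead of
    erroring, so constant demographics tables are handled gracefully.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    samples = [s[np.isfinite(s)] for s in samples]
    if len(samples) < 2 or any(s.size < 1 for s in samples):
        raise InsufficientDataError("need >=2 groups with >=1 observation each")
    if sum(s.size for s in samples) < 3:
        raise InsufficientDataError("need >=3 observations in total")
    labels = tuple(labels) if labels is not None else tuple(
        f"group{i}" for i in range(len(samples)))
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return GroupComparisonResult(0.0, 1.0, "kruskal_wallis", labels,
                                     tuple(s.size for s in samples))
    h, p = sps.kruskal(*samples)
    return GroupComparisonResult(float(h), float(p), "kruskal_wallis", labels,
                                 tuple(s.size for s in samples))


#: sample-size bound below which the exact Mann-Whitney null is enumerated
_EXACT_MW_MAX_N = 8


def _normality_rejected(x: np.ndarray, alpha: float = 0.05) -> bool:
    if x.size < 3 or np.all(x == x[0]):
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bool(sps.shapiro(x).pvalue < alpha)


def two_group_compare(a, b, mode: str = "auto") -> GroupComparisonResult:
    """Welch t or Mann-Whitney U between two samples.

    ``mode='auto'`` picks Mann-Whitney when a Shapiro-Wilk screen rejects
    normality at 0.05 in either sample, Welch otherwise; the chosen test is
    recorded in the result. Mann-Whitney uses the exact null for
    min(n) <= 8 without ties, the tie/continuity-corrected normal
    approximation otherwise. Zero variance in both samples makes Welch
    undefined, falling back to Mann-Whitney with a warning.
    """
    if mode not in ("auto", "welch", "mann_whitney"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
    if xa.size < 2 or xb.size < 2:
        raise InsufficientDataError("need >=2 observations per group")
    chosen = mode
    if mode == "auto":
        chosen = "mann_whitney" if (_normality_rejected(xa) or _normality_rejected(xb)) \
            else "welch"
    if chosen == "welch" and xa.var() == 0 and xb.var() == 0:
        log.warning("two_group_compare: zero variance in both samples, "
                    "falling back to Mann-Whitney")
        chosen = "mann_whitney"
    n = (xa.size, xb.size)
    if chosen == "welch":
        t, p = sps.ttest_ind(xa, xb, equal_var=False)
        return GroupComparisonResult(float(t), float(p), "welch", ("a", "b"), n)
    pooled = np.concatenate([xa, xb])
    if np.all(pooled == pooled[0]):  # fully degenerate: no ordering information
        return GroupComparisonResult(xa.size * xb.size / 2.0, 1.0,
                                     "mann_whitney_degenerate", ("a", "b"), n)
    has_ties = np.unique(pooled).size < xa.size + xb.size
    method = "exact" if (min(n) <= _EXACT_MW_MAX_N and not has_ties) else "asymptotic"
    u, p = sps.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
    return GroupComparisonResult(float(u), float(min(p, 1.0)),
                                 f"mann_whitney_{method}", ("a", "b"), n)


def pearson_with_holm(named_pairs: dict, alpha: float = 0.05) -> list[CorrelationResult]:
    """Pearson r per (feature, MMSE) pair with Holm step-down over the family.

    ``named_pairs`` maps a feature name to an ``(x, y)`` pair of sequences;
    incomplete observations are dropped pairwise (MMSE is missing for a
    sizeable minority of subjects). Zero-variance inputs yield an undefined
    (NaN) r flagged non-significant.
    """
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must be in (0, 1)")
    names, rs, ps, ns = [], [], [], []
    for name, (x, y) in named_pairs.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size:
            raise InvalidParameterError(f"pair {name!r}: unequal lengths")
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3:
            raise InsufficientDataError(f"pair {name!r}: need >=3 complete observations")
        names.append(name)
        ns.append(int(x.size))
        if x.var() == 0 or y.var() == 0:
            log.warning("pearson_with_holm: zero variance in pair %r", name)
            rs.append(np.nan)
            ps.append(np.nan)
            continue
        r, p = sps.pearsonr(x, y)
        rs.append(float(r))
        ps.append(float(p))
    ps_arr = np.asarray(ps)
    testable = np.isfinite(ps_arr)
    significant = np.zeros(len(names), dtype=bool)
    if testable.any():
        significant[testable] = multipletests(ps_arr[testable], alpha=alpha,
                                              method="holm")[0]
    return [CorrelationResult(name=nm, r=r, p=p, holm_significant=bool(sig), n=nn)
            for nm, r, p, sig, nn in zip(names, rs, ps, significant, ns)]


def scale_to_reference(values_by_group: dict, reference: str = "SCD") -> dict:
    """Re-express every group's values relative to the reference group:
    scaled = (x - mean_ref) / SE_ref with SE_ref = SD_ref / sqrt(n_ref).

    By construction the reference group scales to mean 0 and standard
    error 1, which is the bar-plot convention for cross-modality display.
    """
    if reference not in values_by_group:
        raise InvalidParameterError(f"reference group {reference!r} missing")
    ref = np.asarray(values_by_group[reference], dtype=float)
    ref = ref[np.isfinite(ref)]
    if ref.size < 2:
        raise InsufficientDataError("reference group needs >=2 observations")
    se = ref.std(ddof=1) / np.sqrt(ref.size)
    if se == 0:
        raise InvalidParameterError("reference standard error is zero")
    mean = ref.mean()
    return {g: (np.asarray(v, dtype=float) - mean) / se
            for g, v in values_by_group.items()}
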