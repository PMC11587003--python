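"""Significance pipeline for the EFI: variance-equality testing, q-values,
classification, and the comparison / sensitivity analyses.

Equality of the young and elderly difference spreads at a site is tested
with Levene's test (median-centered by default, i.e. the Brown-Forsythe
variant): absolute deviations from each group's center are compared with a
one-way ANOVA F on 1 and n1+n2-2 degrees of freedom. Multiplicity across
sites is handled with Storey's q-values (pi0 estimated on a lambda grid
with the cubic-smoother extrapolation). Sites with q below the significance
level are classified as elderly-significant (EFI > 1) or young-significant
(EFI < 1).

The matrix-scale Levene test is implemented here as vectorised numpy
reductions so that a 450K-scale run is a handful of array passes; the
scalar two-group entry point :func:`levene_p` uses the same arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    MethylationMatrix,
    TwinCohort,
    ValidationError,
    logger,
)
from .efi_core import (
    AgeSplit,
    DifferenceMatrices,
    EfiTable,
    build_differences,
    efi_from_differences,
    split_by_age,
)

Center = Literal["median", "mean"]

SITE_CLASSES = ("elderly-significant", "young-significant", "not-significant", "excluded")

DEFAULT_ALPHA = 0.01
DEFAULT_LAMBDA_GRID = np.arange(0.0, 0.95, 0.05)  # 0, 0.05, ..., 0.90


# ---------------------------------------------------------------------------
# Levene / Brown-Forsythe test
# ---------------------------------------------------------------------------


def _row_nanmedian_sorted(d: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Row-wise median of the non-NaN entries via one sort (NaNs sort last)."""
    s = np.sort(d, axis=1)
    rows = np.arange(d.shape[0])
    lo = np.maximum((n - 1) // 2, 0)
    hi = np.maximum(n // 2, 0)
    med = 0.5 * (s[rows, lo] + s[rows, hi])
    med[n == 0] = np.nan
    return med


def _row_center(d: np.ndarray, n: np.ndarray, center: Center) -> np.ndarray:
    if center == "median":
        return _row_nanmedian_sorted(d, n)
    if center == "mean":
        with np.errstate(invalid="ignore"):
            return np.nansum(d, axis=1, dtype=np.float64) / n
    raise ValidationError(f"center must be 'median' or 'mean', got {center!r}")


def levene_p_matrix(
    d_young: np.ndarray,
    d_elderly: np.ndarray,
    center: Center = "median",
) -> np.ndarray:
    """Row-wise two-group Levene p-values (NaN-aware).

    Per site: absolute deviations Z from the group center, then the one-way
    ANOVA F statistic on Z with an F(1, n1+n2-2) reference. Rows with fewer
    than two valid values in either group get NaN. Rows where all deviations
    are zero in both groups (identical constant spread) get p = 1 by
    convention; zero within-group scatter with nonzero between-group
    separation gets p = 0.
    """
    n1 = np.sum(~np.isnan(d_young), axis=1)
    n2 = np.sum(~np.isnan(d_elderly), axis=1)
    c1 = _row_center(d_young, n1, center)
    c2 = _row_center(d_elderly, n2, center)
    z1 = np.abs(d_young - c1[:, None])
    z2 = np.abs(d_elderly - c2[:, None])
    with np.errstate(invalid="ignore", divide="ignore"):
        z1bar = np.nansum(z1, axis=1, dtype=np.float64) / n1
        z2bar = np.nansum(z2, axis=1, dtype=np.float64) / n2
        zbar = (n1 * z1bar + n2 * z2bar) / (n1 + n2)
        ssb = n1 * (z1bar - zbar) ** 2 + n2 * (z2bar - zbar) ** 2
        ssw = (
            np.nansum(np.square(z1 - z1bar[:, None], dtype=np.float64), axis=1)
            + np.nansum(np.square(z2 - z2bar[:, None], dtype=np.float64), axis=1)
        )
        df2 = n1 + n2 - 2
        w = ssb * df2 / ssw
        p = stats.f.sf(w, 1, df2)
    zero_ssw = ssw == 0
    p = np.where(zero_ssw & (ssb > 0), 0.0, p)
    p = np.where(zero_ssw & (ssb == 0), 1.0, p)
    p = np.where((n1 < 2) | (n2 < 2), np.nan, p)
    return np.asarray(p, dtype=float)


def levene_p(diffs_young, diffs_elderly, center: Center = "median") -> float:
    """Two-sided Levene p for two difference sets (median-centered default).

    Each group needs at least two values. If every absolute deviation is
    zero in both groups, the statistic is 0/0 and p = 1 by convention (no
    evidence either way).
    """
    a = np.asarray(diffs_young, dtype=float)
    b = np.asarray(diffs_elderly, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values for Levene's test")
    p = levene_p_matrix(a[None, :], b[None, :], center=center)[0]
    return float(p)


# ---------------------------------------------------------------------------
# Storey's q-values
# ---------------------------------------------------------------------------


@dataclass
class QValueModel:
    """Storey FDR fit: estimated null proportion pi0, the lambda grid used,
    and q-values aligned to the input p-values."""

    pi0: float
    lambda_grid: np.ndarray
    qvalues: np.ndarray


def estimate_pi0(pvalues: np.ndarray, lambda_grid: np.ndarray | None = None) -> float:
    """Estimate the proportion of true nulls from the p-value distribution.

    For each lambda, pi0(lambda) = #{p > lambda} / (m (1 - lambda)); a cubic
    least-squares smoother over the grid is evaluated at the largest lambda
    and clipped to (0, 1]. With a single lambda the raw estimate is used.
    """
    p = np.asarray(pvalues, dtype=float)
    lam = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    if lam.ndim == 0:
        lam = lam[None]
    if np.any((lam < 0) | (lam >= 1)):
        raise ValidationError("lambda grid values must lie in [0, 1)")
    m = p.size
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    if lam.size == 1:
        pi0 = pi0_lam[0]
    elif lam.size < 4:
        pi0 = pi0_lam[-1]
    else:
        coef = np.polyfit(lam, pi0_lam, deg=3)
        pi0 = float(np.polyval(coef, lam.max()))
    pi0 = min(pi0, 1.0)
    if pi0 <= 0:
        logger.warning("pi0 smoother gave %.3g <= 0; clipping to a small positive value", pi0)
        pi0 = max(pi0, 1.0 / m)
    return float(pi0)


def storey_qvalues(
    pvalues,
    lambda_grid: np.ndarray | None = None,
    pi0: float | None = None,
) -> QValueModel:
    """Storey q-values for a family of p-values.

    q for the i-th smallest p is min over j >= i of pi0 * m * p_(j) / j,
    capped at 1 and returned in input order. ``pi0`` may be fixed (pi0 = 1
    reduces the procedure to Benjamini-Hochberg); otherwise it is estimated
    by :func:`estimate_pi0`.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("need at least one p-value")
    if not np.all(np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must be finite and in [0, 1]")
    lam = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    if pi0 is None:
        pi0_hat = estimate_pi0(p, lam)
    else:
        if not 0 < pi0 <= 1:
            raise ValidationError("pi0 must be in (0, 1]")
        pi0_hat = float(pi0)
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate((pi0_hat * m * p_sorted / ranks)[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueModel(pi0=pi0_hat, lambda_grid=lam, qvalues=q)


# ---------------------------------------------------------------------------
# Classification and the end-to-end analysis
# ---------------------------------------------------------------------------


def classify_sites(
    efi: np.ndarray,
    qvalues: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
) -> np.ndarray:
    """Assign a significance class per site.

    q < alpha with EFI > 1 is elderly-significant, with EFI < 1
    young-significant; otherwise not-significant. Sites with undefined EFI
    or q (NaN) are excluded.
    """
    efi = np.asarray(efi, dtype=float)
    q = np.asarray(qvalues, dtype=float)
    if efi.shape != q.shape:
        raise ValidationError(
            f"EFI and q-value arrays differ in length ({efi.size} vs {q.size})"
        )
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    cls = np.full(efi.shape, "not-significant", dtype=object)
    with np.errstate(invalid="ignore"):
        sig = q < alpha
        cls[sig & (efi > 1)] = "elderly-significant"
        cls[sig & (efi < 1)] = "young-significant"
        cls[np.isnan(efi) | np.isnan(q)] = "excluded"
    return cls


@dataclass
class AnalysisResult:
    """End-to-end per-site analysis: the result table plus run metadata."""

    results: pd.DataFrame  # columns = data_model.RESULT_COLUMNS
    split: AgeSplit
    qmodel: QValueModel
    n_dropped_low_validity: int

    def summary(self) -> dict:
        counts = self.results["class"].value_counts().to_dict()
        defined = self.results["efi"].dropna()
        return {
            "n_sites": int(len(self.results)),
            "n_dropped_low_validity": int(self.n_dropped_low_validity),
            "counts_per_class": {c: int(counts.get(c, 0)) for c in SITE_CLASSES},
            "median_efi": float(defined.median()) if len(defined) else None,
            "fraction_efi_above_1": float((defined > 1).mean()) if len(defined) else None,
            "pi0": float(self.qmodel.pi0),
            "age_cutoff": float(self.split.cutoff),
            "n_young_pairs": len(self.split.young_pair_ids),
            "n_elderly_pairs": len(self.split.elderly_pair_ids),
        }


def analyze_cohort(
    matrix: MethylationMatrix,
    cohort: TwinCohort,
    age_cutoff: float | str = "median",
    alpha: float = DEFAULT_ALPHA,
    min_valid_fraction: float = 0.5,
    difference_mode: str = "signed",
    ddof: int = 1,
    center: Center = "median",
    pi0: float | None = None,
    lambda_grid: np.ndarray | None = None,
) -> AnalysisResult:
    """Run the full per-site pipeline: filter, split, EFI, Levene, Storey,
    classify.

    Sites with undefined EFI (zero young spread or too few valid pairs) are
    excluded before q-value estimation so the FDR family contains only
    tested sites; they appear in the output with class ``excluded`` and NA
    p/q.
    """
    split = split_by_age(cohort, age_cutoff)
    dm = build_differences(matrix, cohort, split, min_valid_fraction)
    efi_tab = efi_from_differences(dm, difference_mode=difference_mode, ddof=ddof)

    p = levene_p_matrix(dm.d_young, dm.d_elderly, center=center)
    tested = efi_tab.defined & np.isfinite(p)
    q = np.full(p.shape, np.nan)
    if tested.sum() == 0:
        raise ValidationError("no testable site: every EFI is undefined")
    qmodel = storey_qvalues(p[tested], lambda_grid=lambda_grid, pi0=pi0)
    q[tested] = qmodel.qvalues
    p = np.where(tested, p, np.nan)
    cls = classify_sites(efi_tab.efi, q, alpha=alpha)

    results = pd.DataFrame(
        {
            "probe": efi_tab.site_ids,
            "n_valid_pairs_young": efi_tab.n_young,
            "n_valid_pairs_elderly": efi_tab.n_elderly,
            "sd_young": efi_tab.sd_young,
            "sd_elderly": efi_tab.sd_elderly,
            "efi": efi_tab.efi,
            "p_levene": p,
            "q_storey": q,
            "class": cls,
        }
    )
    return AnalysisResult(
        results=results,
        split=split,
        qmodel=qmodel,
        n_dropped_low_validity=efi_tab.n_dropped_low_validity,
    )


# ---------------------------------------------------------------------------
# Comparison and sensitivity analyses
# ---------------------------------------------------------------------------


def age_correlation(matrix: MethylationMatrix, cohort: TwinCohort) -> pd.Series:
    """Per-site Pearson correlation between beta and subject age.

    Every subject carries its pair's age. Sites with fewer than three
    present values or zero beta variance are undefined (NaN).
    """
    subj_cols = np.array([matrix.subject_index(s) for s in cohort.subject_ids])
    ages = np.repeat(cohort.ages, 2)
    b = matrix.beta[:, subj_cols].astype(np.float64, copy=True)
    present = ~np.isnan(b)
    n = present.sum(axis=1)
    b_filled = np.where(present, b, 0.0)
    a_mat = np.where(present, ages[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mb = b_filled.sum(axis=1) / n
        ma = a_mat.sum(axis=1) / n
        db = np.where(present, b - mb[:, None], 0.0)
        da = np.where(present, ages[None, :] - ma[:, None], 0.0)
        cov = (db * da).sum(axis=1)
        vb = (db * db).sum(axis=1)
        va = (da * da).sum(axis=1)
        r = cov / np.sqrt(vb * va)
    r[(n < 3) | (vb == 0) | (va == 0)] = np.nan
    return pd.Series(r, index=matrix.probe_ids, name="age_correlation")


def cutoff_sensitivity(
    matrix: MethylationMatrix,
    cohort: TwinCohort,
    cutoffs: Sequence[float | str],
    min_valid_fraction: float = 0.5,
    difference_mode: str = "signed",
    ddof: int = 1,
) -> pd.DataFrame:
    """Pearson correlations between EFI vectors computed at different age
    cutoffs.

    The EFI is recomputed per cutoff; correlations are taken over the common
    set of sites with a defined EFI at every cutoff. The returned square
    DataFrame includes a ``median`` baseline column/row when not already in
    the list, so the first row gives each cutoff's agreement with the
    median-split analysis.
    """
    labels: list[str] = []
    cut_list: list[float | str] = []
    if not any(c == "median" for c in cutoffs):
        cut_list.append("median")
        labels.append("median")
    for c in cutoffs:
        cut_list.append(c)
        labels.append(str(c))
    if len(cut_list) < 2:
        raise ValidationError("need at least two cutoffs to compare")

    efi_vectors = {}
    common: np.ndarray | None = None
    for label, cut in zip(labels, cut_list):
        try:
            split = split_by_age(cohort, cut)
        except ValidationError as exc:
            raise ValidationError(f"cutoff {label}: {exc}") from None
        tab = efi_from_differences(
            build_differences(matrix, cohort, split, min_valid_fraction),
            difference_mode=difference_mode,
            ddof=ddof,
        )
        s = pd.Series(tab.efi, index=tab.site_ids)
        efi_vectors[label] = s
        mask_idx = s.index[tab.defined]
        common = mask_idx if common is None else common.intersection(mask_idx)
    if common is None or len(common) < 3:
        raise ValidationError("fewer than 3 sites have defined EFI at all cutoffs")
    aligned = pd.DataFrame({lab: efi_vectors[lab].loc[common] for lab in labels})
    return aligned.corr(method="pearson")


def subset_summary(site_results: pd.DataFrame, probe_list) -> dict:
    """EFI summary over a probe list (e.g. an epigenetic-clock site panel).

    Returns matched/unmatched counts, how many matched sites are significant
    (either class), and mean/SD of the defined EFIs among matched sites.
    """
    probes = list(probe_list)
    if not probes:
        raise ValidationError("probe list is empty")
    wanted = set(probes)
    sub = site_results[site_results["probe"].isin(wanted)]
    n_unmatched = len(wanted) - sub["probe"].nunique()
    if len(sub) == 0:
        raise ValidationError("no probe of the list is present in the results")
    if n_unmatched:
        logger.warning("%d probes of the list are absent from the results", n_unmatched)
    sig = sub["class"].isin(("elderly-significant", "young-significant"))
    defined = sub["efi"].dropna()
    return {
        "n_sites": int(len(sub)),
        "n_unmatched": int(n_unmatched),
        "n_significant": int(sig.sum()),
        "mean_efi": float(defined.mean()) if len(defined) else None,
        "sd_efi": float(defined.std(ddof=1)) if len(defined) > 1 else None,
    }
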