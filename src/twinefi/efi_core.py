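"""Core of the Environmental Factor Index (EFI).

For every methylation site the within-pair methylation differences of
monozygotic twins are split into a young and an elderly group by a pair-age
cutoff (median age by default). The EFI of a site is the ratio of the
standard deviation of those differences in the elderly group to that in the
young group:

    EFI = SD(differences, elderly pairs) / SD(differences, young pairs)

EFI = 1 means age-neutral spread; EFI > 1 means twin discordance at the site
grows with age (the signature expected of cumulative environmental
exposure); EFI < 1 means it shrinks.

Everything here is vectorised over sites so a full 450K-scale matrix
(~4.8e5 probes x ~500 subjects) is processed in one pass of numpy
reductions; missing entries are NaN throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal, Sequence

import numpy as np

from .data_model import (
    InsufficientDataError,
    MethylationMatrix,
    TwinCohort,
    ValidationError,
    logger,
)

DifferenceMode = Literal["signed", "rms"]


# ---------------------------------------------------------------------------
# Age split
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeSplit:
    """Partition of a cohort's pairs into an elderly (age >= cutoff) and a
    young (age < cutoff) group."""

    cutoff: float
    elderly_pair_ids: tuple[str, ...]
    young_pair_ids: tuple[str, ...]


def split_by_age(cohort: TwinCohort, cutoff: float | str = "median") -> AgeSplit:
    """Split pairs at an age cutoff; ``"median"`` uses the median pair age.

    A pair whose age equals the cutoff is elderly. Raises
    :class:`ValidationError` if either group would be empty (a degenerate
    split leaves nothing to compare).
    """
    ages = cohort.ages
    if isinstance(cutoff, str):
        if cutoff != "median":
            raise ValidationError(f"cutoff must be a number or 'median', got {cutoff!r}")
        cut = float(np.median(ages))
    else:
        cut = float(cutoff)
    elderly = tuple(p.pair_id for p in cohort.pairs if p.age >= cut)
    young = tuple(p.pair_id for p in cohort.pairs if p.age < cut)
    if not elderly or not young:
        raise ValidationError(
            f"degenerate age split at cutoff {cut}: "
            f"{len(young)} young vs {len(elderly)} elderly pairs"
        )
    return AgeSplit(cutoff=cut, elderly_pair_ids=elderly, young_pair_ids=young)


# ---------------------------------------------------------------------------
# Within-pair differences
# ---------------------------------------------------------------------------


@dataclass
class PairDifferenceSet:
    """Per-site signed within-pair differences, grouped by age split.

    Only pairs with both members measured at the site contribute; the
    difference convention is beta(subject_a) - beta(subject_b) in the
    pair-table order.
    """

    site: str
    diffs_young: np.ndarray
    diffs_elderly: np.ndarray
    valid_pair_ids_young: tuple[str, ...]
    valid_pair_ids_elderly: tuple[str, ...]

    @property
    def is_empty(self) -> bool:
        return self.diffs_young.size == 0 and self.diffs_elderly.size == 0


@dataclass
class DifferenceMatrices:
    """Sites x pairs difference matrices for the two age groups (NaN where a
    pair had a missing member), restricted to sites passing the validity
    filter."""

    site_ids: np.ndarray
    d_young: np.ndarray  # (n_sites, n_young_pairs)
    d_elderly: np.ndarray  # (n_sites, n_elderly_pairs)
    young_pair_ids: tuple[str, ...]
    elderly_pair_ids: tuple[str, ...]
    n_dropped_low_validity: int


def _pair_column_indices(matrix: MethylationMatrix, cohort: TwinCohort,
                         pair_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    by_id = {p.pair_id: p for p in cohort.pairs}
    ia = np.array([matrix.subject_index(by_id[pid].subject_a) for pid in pair_ids])
    ib = np.array([matrix.subject_index(by_id[pid].subject_b) for pid in pair_ids])
    return ia, ib


def build_differences(
    matrix: MethylationMatrix,
    cohort: TwinCohort,
    split: AgeSplit,
    min_valid_fraction: float = 0.5,
) -> DifferenceMatrices:
    """Construct the young/elderly difference matrices for all retained sites.

    A site is retained when the fraction of cohort subjects with a present
    beta value is at least ``min_valid_fraction`` (default 0.5, i.e. at
    least half of the subjects measured). The filter runs before pair
    differences are formed; individual pairs with a missing member are then
    dropped per site.
    """
    if not 0 < min_valid_fraction <= 1:
        raise ValidationError("min_valid_fraction must be in (0, 1]")
    subj_cols = np.array([matrix.subject_index(s) for s in cohort.subject_ids])
    n_subjects = subj_cols.size
    valid_counts = np.sum(~np.isnan(matrix.beta[:, subj_cols]), axis=1)
    keep = valid_counts >= min_valid_fraction * n_subjects
    n_dropped = int((~keep).sum())
    beta = matrix.beta[keep]

    ia_y, ib_y = _pair_column_indices(matrix, cohort, split.young_pair_ids)
    ia_e, ib_e = _pair_column_indices(matrix, cohort, split.elderly_pair_ids)
    d_young = beta[:, ia_y] - beta[:, ib_y]
    d_elderly = beta[:, ia_e] - beta[:, ib_e]
    return DifferenceMatrices(
        site_ids=matrix.probe_ids[keep],
        d_young=d_young,
        d_elderly=d_elderly,
        young_pair_ids=split.young_pair_ids,
        elderly_pair_ids=split.elderly_pair_ids,
        n_dropped_low_validity=n_dropped,
    )


def pair_differences(
    matrix: MethylationMatrix,
    cohort: TwinCohort,
    split: AgeSplit,
    site: str,
) -> PairDifferenceSet:
    """Within-pair differences at one site, grouped by the age split.

    Pairs with a missing member at the site are excluded; a site where every
    pair is missing yields an empty (flagged) difference set, not an error.
    """
    row = matrix.beta[matrix.probe_index(site)]
    out: dict[str, tuple[np.ndarray, tuple[str, ...]]] = {}
    for group, pair_ids in (
        ("young", split.young_pair_ids),
        ("elderly", split.elderly_pair_ids),
    ):
        ia, ib = _pair_column_indices(matrix, cohort, pair_ids)
        d = row[ia] - row[ib]
        ok = ~np.isnan(d)
        out[group] = (d[ok], tuple(np.asarray(pair_ids, dtype=object)[ok]))
    ds = PairDifferenceSet(
        site=site,
        diffs_young=out["young"][0],
        diffs_elderly=out["elderly"][0],
        valid_pair_ids_young=out["young"][1],
        valid_pair_ids_elderly=out["elderly"][1],
    )
    if ds.is_empty:
        logger.warning("site %s: no valid pairs at any age; empty difference set", site)
    return ds


# ---------------------------------------------------------------------------
# Spread statistics
# ---------------------------------------------------------------------------


def group_sd(diffs, ddof: int = 1) -> float:
    """Sample standard deviation of a difference set (n-1 denominator by
    default; set ``ddof=0`` for the population form)."""
    d = np.asarray(diffs, dtype=float)
    d = d[~np.isnan(d)]
    if d.size < max(2, ddof + 1):
        raise InsufficientDataError(
            f"need at least {max(2, ddof + 1)} differences, got {d.size}"
        )
    return float(np.std(d, ddof=ddof))


def group_spread(diffs, mode: DifferenceMode = "signed", ddof: int = 1) -> float:
    """Spread of a difference set: sample SD in ``signed`` mode, root mean
    square sqrt(mean(d^2)) in ``rms`` mode (invariant to per-pair sign flips)."""
    if mode == "signed":
        return group_sd(diffs, ddof=ddof)
    if mode == "rms":
        d = np.asarray(diffs, dtype=float)
        d = d[~np.isnan(d)]
        if d.size < 2:
            raise InsufficientDataError(f"need at least 2 differences, got {d.size}")
        return float(np.sqrt(np.mean(d * d)))
    raise ValidationError(f"unknown difference mode {mode!r}")


def _row_spread(d: np.ndarray, n: np.ndarray, mode: DifferenceMode, ddof: int
                ) -> np.ndarray:
    """Row-wise nan-aware spread; NaN where fewer than max(2, ddof+1) values."""
    with np.errstate(invalid="ignore", divide="ignore"):
        if mode == "rms":
            ss = np.nansum(np.square(d, dtype=np.float64), axis=1)
            out = np.sqrt(ss / n)
        else:
            mean = np.nansum(d, axis=1, dtype=np.float64) / n
            dev = d - mean[:, None]
            ss = np.nansum(np.square(dev, dtype=np.float64), axis=1)
            out = np.sqrt(ss / (n - ddof))
    out[n < max(2, ddof + 1)] = np.nan
    return out


# ---------------------------------------------------------------------------
# EFI
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EfiValue:
    """EFI of one site; ``efi`` is None when undefined (sd_young == 0 or too
    few valid pairs in a group)."""

    site: str
    sd_young: float | None
    sd_elderly: float | None
    efi: float | None
    n_young: int
    n_elderly: int


@dataclass
class EfiTable:
    """Column-wise EFI results for all retained sites.

    ``efi`` is NaN where undefined; ``defined`` marks sites with a finite,
    positive-denominator ratio.
    """

    site_ids: np.ndarray
    n_young: np.ndarray
    n_elderly: np.ndarray
    sd_young: np.ndarray
    sd_elderly: np.ndarray
    efi: np.ndarray
    defined: np.ndarray
    n_dropped_low_validity: int = 0

    def __len__(self) -> int:
        return self.site_ids.size

    def __iter__(self) -> Iterator[EfiValue]:
        for k in range(len(self)):
            yield EfiValue(
                site=str(self.site_ids[k]),
                sd_young=None if np.isnan(self.sd_young[k]) else float(self.sd_young[k]),
                sd_elderly=None if np.isnan(self.sd_elderly[k]) else float(self.sd_elderly[k]),
                efi=float(self.efi[k]) if self.defined[k] else None,
                n_young=int(self.n_young[k]),
                n_elderly=int(self.n_elderly[k]),
            )


def efi_from_differences(
    dm: DifferenceMatrices,
    difference_mode: DifferenceMode = "signed",
    ddof: int = 1,
) -> EfiTable:
    """Compute per-site spreads and their elderly/young ratio from prebuilt
    difference matrices."""
    n_y = np.sum(~np.isnan(dm.d_young), axis=1)
    n_e = np.sum(~np.isnan(dm.d_elderly), axis=1)
    sd_y = _row_spread(dm.d_young, n_y, difference_mode, ddof)
    sd_e = _row_spread(dm.d_elderly, n_e, difference_mode, ddof)
    with np.errstate(invalid="ignore", divide="ignore"):
        efi = sd_e / sd_y
    defined = np.isfinite(efi) & (sd_y > 0)
    efi = np.where(defined, efi, np.nan)
    n_undefined = int((~defined).sum())
    if n_undefined:
        logger.info("%d of %d sites have undefined EFI", n_undefined, len(defined))
    return EfiTable(
        site_ids=dm.site_ids,
        n_young=n_y,
        n_elderly=n_e,
        sd_young=sd_y,
        sd_elderly=sd_e,
        efi=efi,
        defined=defined,
        n_dropped_low_validity=dm.n_dropped_low_validity,
    )


def compute_efi(
    matrix: MethylationMatrix,
    cohort: TwinCohort,
    split: AgeSplit,
    min_valid_fraction: float = 0.5,
    difference_mode: DifferenceMode = "signed",
    ddof: int = 1,
) -> EfiTable:
    """EFI for every site passing the validity filter.

    Sites measured in fewer than ``min_valid_fraction`` of subjects are
    dropped; sites whose young-group spread is zero (or with fewer than two
    valid pairs in a group) are kept with an undefined-EFI flag so they can
    be reported as excluded rather than silently vanish.
    """
    dm = build_differences(matrix, cohort, split, min_valid_fraction)
    return efi_from_differences(dm, difference_mode=difference_mode, ddof=ddof)
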