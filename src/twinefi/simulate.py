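"""Synthetic monozygotic-twin methylation cohorts with known EFI ground
truth.

The generator emulates the statistical structure the EFI is built to
detect. Per site s a baseline beta level b_s is drawn from a bimodal
mixture (most 450K probes sit near 0 or near 1); per pair p both twins
share b_s plus a pair-specific offset, and differ by a within-pair
difference d_sp ~ Normal(0, sigma_sp). At null sites sigma_sp is
``sigma_young`` for every pair; at affected sites it is
``true_ratio * sigma_young`` for pairs at or above the generative age
cutoff, so the population EFI of an affected site equals ``true_ratio``.
Values are clipped to [0, 1] (clip events are counted and high-clip sites
warned about) and entries are masked missing independently at
``missing_rate``. Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    MethylationMatrix,
    TwinCohort,
    TwinPair,
    ValidationError,
    logger,
)

# chunk of sites drawn at a time; bounds peak memory at full 450K scale
_CHUNK_SITES = 50_000


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror a 450K MZ-twin study: 245 pairs with ages uniform on
    [20, 86] years (median 53, quartiles near 36 and 70), within-pair
    difference SD 0.02 beta units in the young group, 5% of sites affected
    with a true SD ratio of 2, and 2% missingness.
    """

    n_pairs: int = 245
    n_sites: int = 10_000
    fraction_affected: float = 0.05
    true_ratio: float = 2.0
    sigma_young: float = 0.02
    sigma_pair: float = 0.03  # SD of the shared pair offset around the site baseline
    missing_rate: float = 0.02
    seed: int = 0
    age_range: tuple[float, float] = (20.0, 86.0)
    ages: tuple[float, ...] | None = None  # explicit ages override age_range
    generative_cutoff: float | None = None  # None -> median of drawn ages
    base_beta_modes: tuple[tuple[float, float], ...] = ((1.5, 8.0), (8.0, 1.5))
    clip: bool = True
    p_female: float = 178 / 245

    def __post_init__(self) -> None:
        if self.true_ratio <= 0:
            raise ValidationError("true_ratio must be > 0")
        if not 0 <= self.fraction_affected <= 1:
            raise ValidationError("fraction_affected must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.sigma_young <= 0:
            raise ValidationError("sigma_young must be > 0")
        if self.n_pairs < 2 or self.n_sites < 1:
            raise ValidationError("need at least 2 pairs and 1 site")


@dataclass
class SimulatedCohort:
    """A generated cohort plus its ground truth."""

    matrix: MethylationMatrix
    cohort: TwinCohort
    truth: pd.DataFrame  # columns: probe, affected, true_ratio
    config: SimulationConfig
    n_clipped: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    generative_cutoff: float = float("nan")


def _draw_ages(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.ages is not None:
        ages = np.asarray(cfg.ages, dtype=float)
        if ages.size != cfg.n_pairs:
            raise ValidationError(
                f"ages list has {ages.size} entries for {cfg.n_pairs} pairs"
            )
        return ages
    lo, hi = cfg.age_range
    if not hi > lo >= 0:
        raise ValidationError(f"invalid age range {cfg.age_range}")
    return rng.uniform(lo, hi, size=cfg.n_pairs)


def _draw_baselines(cfg: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    modes = cfg.base_beta_modes
    comp = rng.integers(0, len(modes), size=n)
    out = np.empty(n)
    for k, (a, b) in enumerate(modes):
        sel = comp == k
        out[sel] = rng.beta(a, b, size=int(sel.sum()))
    return out


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort under the configured study conditions.

    The beta matrix has one column per subject, pair members adjacent
    (``P0001a``, ``P0001b``, ...). Ground truth marks each site affected or
    null with its true SD ratio. Sites where more than half of the values
    hit the [0, 1] clip are warned about: clipping compresses the very
    spread the EFI measures.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ages = _draw_ages(cfg, rng)
    cutoff = float(np.median(ages)) if cfg.generative_cutoff is None else float(cfg.generative_cutoff)
    old_pair = ages >= cutoff

    width = max(4, len(str(cfg.n_pairs)))
    pair_ids = [f"P{k + 1:0{width}d}" for k in range(cfg.n_pairs)]
    sexes = np.where(rng.random(cfg.n_pairs) < cfg.p_female, "F", "M")
    pairs = [
        TwinPair(pid, f"{pid}a", f"{pid}b", float(age), str(sex))
        for pid, age, sex in zip(pair_ids, ages, sexes)
    ]
    cohort = TwinCohort(pairs)

    affected = np.zeros(cfg.n_sites, dtype=bool)
    n_aff = int(round(cfg.fraction_affected * cfg.n_sites))
    if n_aff:
        affected[rng.choice(cfg.n_sites, size=n_aff, replace=False)] = True

    beta = np.empty((cfg.n_sites, 2 * cfg.n_pairs), dtype=np.float32)
    n_clipped = np.zeros(cfg.n_sites, dtype=np.int64)
    for start in range(0, cfg.n_sites, _CHUNK_SITES):
        stop = min(start + _CHUNK_SITES, cfg.n_sites)
        m = stop - start
        b_s = _draw_baselines(cfg, rng, m)
        pair_level = b_s[:, None] + rng.normal(0.0, cfg.sigma_pair, size=(m, cfg.n_pairs))
        sigma = np.full((m, cfg.n_pairs), cfg.sigma_young)
        sigma[np.ix_(affected[start:stop], old_pair)] *= cfg.true_ratio
        d = rng.standard_normal((m, cfg.n_pairs)) * sigma
        twin_a = pair_level + d / 2.0
        twin_b = pair_level - d / 2.0
        block = np.empty((m, 2 * cfg.n_pairs))
        block[:, 0::2] = twin_a
        block[:, 1::2] = twin_b
        if cfg.clip:
            clipped = (block < 0.0) | (block > 1.0)
            n_clipped[start:stop] = clipped.sum(axis=1)
            np.clip(block, 0.0, 1.0, out=block)
        if cfg.missing_rate > 0:
            block[rng.random(block.shape) < cfg.missing_rate] = np.nan
        beta[start:stop] = block

    high_clip = n_clipped > beta.shape[1] / 2
    if high_clip.any():
        for idx in np.flatnonzero(high_clip)[:20]:
            logger.warning(
                "site cg%08d: %d of %d values clipped to [0, 1]; its spread is distorted",
                idx, n_clipped[idx], beta.shape[1],
            )

    probe_ids = np.array([f"cg{k:08d}" for k in range(cfg.n_sites)], dtype=object)
    subject_ids = [s for p in pairs for s in (p.subject_a, p.subject_b)]
    matrix = MethylationMatrix(probe_ids=probe_ids, subject_ids=subject_ids,
                               beta=beta, check_range=cfg.clip)
    truth = pd.DataFrame(
        {
            "probe": probe_ids,
            "affected": affected,
            "true_ratio": np.where(affected, cfg.true_ratio, 1.0),
        }
    )
    return SimulatedCohort(
        matrix=matrix,
        cohort=cohort,
        truth=truth,
        config=cfg,
        n_clipped=n_clipped,
        generative_cutoff=cutoff,
    )


def null_config(**overrides) -> SimulationConfig:
    """A pure-null configuration (no affected sites); keyword overrides
    apply on top."""
    return replace(SimulationConfig(fraction_affected=0.0, true_ratio=1.0), **overrides)


def recovery_report(
    simulated: SimulatedCohort,
    alpha: float = 0.01,
    raw_alpha: float = 0.05,
    **pipeline_kwargs,
) -> dict:
    """Run the full pipeline on a simulated cohort and score it against the
    ground truth.

    Reports the raw-p rejection rate among null sites (type I error), the
    q-threshold detection rate among affected sites (power), the realized
    FDR among q-significant calls, and the median bias of the estimated EFI
    at affected sites.
    """
    from .inference import analyze_cohort  # local import: avoids cycle at import time

    res = analyze_cohort(
        simulated.matrix, simulated.cohort, alpha=alpha, **pipeline_kwargs
    ).results
    merged = res.merge(simulated.truth, on="probe", how="left")
    null_mask = ~merged["affected"].astype(bool)
    aff_mask = merged["affected"].astype(bool)
    sig = merged["class"].isin(("elderly-significant", "young-significant"))
    p = merged["p_levene"]

    null_tested = null_mask & p.notna()
    type_i = float((p[null_tested] < raw_alpha).mean()) if null_tested.any() else float("nan")
    power = float(sig[aff_mask].mean()) if aff_mask.any() else float("nan")
    n_calls = int(sig.sum())
    false_calls = int((sig & null_mask).sum())
    observed_fdr = false_calls / n_calls if n_calls else 0.0
    k = simulated.config.true_ratio
    efi_aff = merged.loc[aff_mask, "efi"].dropna()
    efi_bias = float((efi_aff - k).median()) if len(efi_aff) else float("nan")
    return {
        "type_I_error": type_i,
        "power": power,
        "observed_fdr": observed_fdr,
        "efi_bias": efi_bias,
        "n_significant_calls": n_calls,
        "n_false_calls": false_calls,
        "median_efi_affected": float(efi_aff.median()) if len(efi_aff) else float("nan"),
        "n_null_tested": int(null_tested.sum()),
        "n_affected": int(aff_mask.sum()),
    }
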