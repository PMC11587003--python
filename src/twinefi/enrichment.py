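"""Downstream analyses over significant sites: site/gene rankings,
elite-gene coincidence testing, marker-panel binomial tests, and the CpG
feature tabulation.

A "significant" site is one classified elderly- or young-significant by the
inference stage; a gene is a "hit" when at least one significant site maps
to it. A probe annotated to several genes counts toward every one of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    CPG_FEATURES,
    ProbeAnnotation,
    ValidationError,
    logger,
)

SIGNIFICANT_CLASSES = ("elderly-significant", "young-significant")


def _significant_mask(site_results: pd.DataFrame) -> pd.Series:
    return site_results["class"].isin(SIGNIFICANT_CLASSES)


# ---------------------------------------------------------------------------
# Rankings
# ---------------------------------------------------------------------------


def rank_sites(site_results: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """Top-n sites by EFI (defined EFIs only), descending.

    Ties break by ascending q then probe id, so the ordering is
    deterministic. Asking for more sites than exist returns all with a
    warning.
    """
    defined = site_results.dropna(subset=["efi"]).copy()
    if n > len(defined):
        logger.warning("requested top %d sites but only %d have defined EFI", n, len(defined))
        n = len(defined)
    defined["_neg_efi"] = -defined["efi"]
    out = defined.sort_values(
        ["_neg_efi", "q_storey", "probe"], kind="mergesort"
    ).head(n)
    return out.drop(columns="_neg_efi").reset_index(drop=True)


@dataclass(frozen=True)
class GeneSiteCount:
    """Number of significant sites mapping to one gene."""

    gene: str
    n_significant_sites: int
    is_elite: bool = False


def count_significant_sites_per_gene(
    site_results: pd.DataFrame, annotation: ProbeAnnotation
) -> dict[str, int]:
    counts: dict[str, int] = {}
    sig_probes = site_results.loc[_significant_mask(site_results), "probe"]
    for probe in sig_probes:
        for gene in annotation.genes_of(str(probe)):
            counts[gene] = counts.get(gene, 0) + 1
    return counts


def rank_genes(
    site_results: pd.DataFrame,
    annotation: ProbeAnnotation,
    n: int = 10,
    elite_genes: frozenset[str] | set[str] = frozenset(),
) -> list[GeneSiteCount]:
    """Top-n genes by number of significant sites (descending, ties by
    symbol)."""
    counts = count_significant_sites_per_gene(site_results, annotation)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        GeneSiteCount(gene=g, n_significant_sites=c, is_elite=g in elite_genes)
        for g, c in ranked[:n]
    ]


def gene_is_hit(
    gene: str, site_results: pd.DataFrame, annotation: ProbeAnnotation
) -> bool:
    """True iff at least one significant site (either class) maps to the
    gene; a symbol with no probe in the annotation is a non-hit with a
    warning."""
    if gene not in annotation.all_genes():
        logger.warning("gene %s has no probe in the annotation; counted as non-hit", gene)
        return False
    counts = count_significant_sites_per_gene(site_results, annotation)
    return counts.get(gene, 0) >= 1


# ---------------------------------------------------------------------------
# Elite-gene coincidence test
# ---------------------------------------------------------------------------


@dataclass
class BackgroundSample:
    """Genes reached by a uniform random draw of probes, with elite count."""

    n_sites: int
    genes: frozenset[str]
    n_genes: int
    n_elite: int

    @property
    def elite_ratio(self) -> float:
        return self.n_elite / self.n_genes if self.n_genes else float("nan")


def sample_background(
    probe_ids,
    annotation: ProbeAnnotation,
    n_sites: int,
    seed: int | np.random.Generator,
    elite_genes: frozenset[str] | set[str],
) -> BackgroundSample:
    """Draw ``n_sites`` probes uniformly without replacement, map them to
    distinct genes, and count how many genes are elite.

    Mirrors the construction of an empirical background elite-gene rate
    when the catalogue itself does not publish one.
    """
    probes = np.asarray(probe_ids, dtype=object)
    if n_sites > probes.size:
        raise ValidationError(f"cannot sample {n_sites} of {probes.size} probes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(probes, size=n_sites, replace=False)
    genes: set[str] = set()
    for p in chosen:
        genes |= annotation.genes_of(str(p))
    n_elite = len(genes & set(elite_genes))
    return BackgroundSample(
        n_sites=n_sites, genes=frozenset(genes), n_genes=len(genes), n_elite=n_elite
    )


@dataclass
class EnrichmentResult:
    """2x2 elite-gene coincidence test.

    ``table`` is [[focal_elite, focal_non_elite], [bg_elite, bg_non_elite]];
    ``odds_ratio`` is the sample cross-product ratio ad/bc (NaN when a
    margin is zero); ``p`` is the two-sided Fisher exact probability (sum of
    table probabilities no larger than the observed one).
    """

    table: np.ndarray
    odds_ratio: float
    p: float


def elite_fisher(
    focal_elite: int, focal_total: int, bg_elite: int, bg_total: int
) -> EnrichmentResult:
    """Two-tailed Fisher's exact test of elite-gene excess in a focal gene
    list against a background list."""
    if not (0 <= focal_elite <= focal_total and 0 <= bg_elite <= bg_total):
        raise ValidationError("counts must satisfy 0 <= elite <= total")
    a, b = focal_elite, focal_total - focal_elite
    c, d = bg_elite, bg_total - bg_elite
    table = np.array([[a, b], [c, d]], dtype=int)
    if min(a + b, c + d, a + c, b + d) == 0:
        return EnrichmentResult(table=table, odds_ratio=float("nan"), p=1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        oratio = (a * d) / (b * c) if b * c else float("inf")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(table=table, odds_ratio=float(oratio), p=float(p))


def elite_fisher_conditional_or(result: EnrichmentResult) -> float:
    """Conditional maximum-likelihood odds ratio for an already computed
    2x2 table (alternative estimator; the sample ratio is the default)."""
    return float(stats.contingency.odds_ratio(result.table, kind="conditional").statistic)


# ---------------------------------------------------------------------------
# Marker-panel binomial test
# ---------------------------------------------------------------------------


def marker_binomial(n_markers: int, n_hit: int, p0: float) -> float:
    """Upper-tail exact binomial probability P(X >= n_hit), X ~ Bin(n_markers, p0).

    ``p0`` is the background probability that a random gene is a hit; it
    must be supplied (or estimated empirically via repeated
    :func:`sample_background` draws).
    """
    if not 0 < p0 < 1:
        raise ValidationError(f"background probability p0 must be in (0, 1), got {p0}")
    if not 0 <= n_hit <= n_markers:
        raise ValidationError("need 0 <= n_hit <= n_markers")
    return float(stats.binom.sf(n_hit - 1, n_markers, p0))


def estimate_background_hit_rate(
    site_results: pd.DataFrame,
    annotation: ProbeAnnotation,
    n_sites: int,
    n_draws: int,
    seed: int,
) -> float:
    """Empirical background gene hit rate: over seeded random probe draws,
    the fraction of reached genes that have at least one significant site."""
    rng = np.random.default_rng(seed)
    counts = count_significant_sites_per_gene(site_results, annotation)
    probes = site_results["probe"].to_numpy(dtype=object)
    hits = total = 0
    for _ in range(n_draws):
        bs = sample_background(probes, annotation, n_sites, rng, frozenset())
        total += bs.n_genes
        hits += sum(1 for g in bs.genes if counts.get(g, 0) >= 1)
    if total == 0:
        raise ValidationError("background draws reached no annotated gene")
    return hits / total


# ---------------------------------------------------------------------------
# CpG feature tabulation
# ---------------------------------------------------------------------------


def cpg_feature_table(
    site_results: pd.DataFrame, annotation: ProbeAnnotation
) -> pd.DataFrame:
    """Counts of sites and significant sites per relation-to-island feature.

    ``pct_in_feature`` = significant / sites within the feature;
    ``pct_in_total`` = the feature's significant sites / all tabulated
    probes. A Total row closes the table; per-feature counts sum exactly to
    it. Features with zero sites report 0 with a zero-denominator flag
    column.
    """
    feats = site_results["probe"].map(lambda p: annotation.feature_of(str(p)))
    sig = _significant_mask(site_results)
    total_probes = len(site_results)
    rows = []
    for feat in CPG_FEATURES:
        in_feat = feats == feat
        n_sites = int(in_feat.sum())
        n_sig = int((in_feat & sig).sum())
        rows.append(
            {
                "feature": feat,
                "n_sites": n_sites,
                "n_significant": n_sig,
                "pct_in_feature": 100.0 * n_sig / n_sites if n_sites else 0.0,
                "pct_in_total": 100.0 * n_sig / total_probes if total_probes else 0.0,
                "zero_denominator": n_sites == 0,
            }
        )
    rows.append(
        {
            "feature": "Total",
            "n_sites": total_probes,
            "n_significant": int(sig.sum()),
            "pct_in_feature": 100.0 * sig.sum() / total_probes if total_probes else 0.0,
            "pct_in_total": 100.0 * sig.sum() / total_probes if total_probes else 0.0,
            "zero_denominator": total_probes == 0,
        }
    )
    return pd.DataFrame(rows)
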