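"""Domain types and delimited-text I/O for twin methylation analyses.

The pipeline consumes four kinds of input, all plain delimited text:

* a beta-value matrix (probes x subjects, values in [0, 1], missing allowed),
* a twin-pair table (pair id, the two subject ids, age in years, sex),
* an Illumina-manifest-style probe annotation (probe -> gene symbols and
  relation to the nearest CpG island),
* plain one-symbol-per-line gene lists (disease "elite" genes, marker panels).

and emits one kind of output, the per-site result table written by
:func:`write_site_results`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("twinefi")

# Missing-value tokens accepted in beta matrices (case-insensitive).
MISSING_TOKENS = ("", "na", "nan")

# The six relation-to-CpG-island categories used in reporting.
CPG_FEATURES = (
    "Island",
    "North Shore",
    "South Shore",
    "North Shelf",
    "South Shelf",
    "Other",
)

# Illumina 450K manifest relation codes -> reporting categories.
RELATION_CODES: Mapping[str, str] = {
    "island": "Island",
    "n_shore": "North Shore",
    "s_shore": "South Shore",
    "n_shelf": "North Shelf",
    "s_shelf": "South Shelf",
    "": "Other",
    "opensea": "Other",
    # canonical category names are accepted as their own codes
    "north shore": "North Shore",
    "south shore": "South Shore",
    "north shelf": "North Shelf",
    "south shelf": "South Shelf",
    "other": "Other",
}

#: Column order of the site-result table, fixed for round-tripping.
RESULT_COLUMNS = (
    "probe",
    "n_valid_pairs_young",
    "n_valid_pairs_elderly",
    "sd_young",
    "sd_elderly",
    "efi",
    "p_levene",
    "q_storey",
    "class",
)


class TwinEfiError(Exception):
    """Base class for all package errors."""


class FormatError(TwinEfiError):
    """A file does not have the expected structure."""


class ValidationError(TwinEfiError):
    """Parsed content violates a domain invariant."""


class InsufficientDataError(TwinEfiError):
    """Too few observations for the requested statistic."""


# ---------------------------------------------------------------------------
# Methylation matrix
# ---------------------------------------------------------------------------


@dataclass
class MethylationMatrix:
    """Probes x subjects beta values; missing entries stored as NaN.

    Beta values are fluorescence-intensity ratios in [0, 1]: 0 means the
    site is unmethylated in every measured cell, 1 means fully methylated.
    """

    probe_ids: np.ndarray  # dtype=object/str, length n_probes
    subject_ids: list[str]
    beta: np.ndarray  # float array (n_probes, n_subjects), NaN = missing
    # diagnostic escape hatch: the simulator's unclipped mode stores values
    # outside [0, 1] on purpose
    check_range: bool = True

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.beta = np.asarray(self.beta)
        if self.beta.ndim != 2:
            raise ValidationError("beta must be a 2-D array")
        n_probes, n_subjects = self.beta.shape
        if n_probes < 1 or n_subjects < 2:
            raise ValidationError("need at least one probe and two subjects")
        if len(self.probe_ids) != n_probes:
            raise ValidationError("probe_ids length does not match beta rows")
        if len(self.subject_ids) != n_subjects:
            raise ValidationError("subject_ids length does not match beta columns")
        if len(set(self.probe_ids)) != n_probes:
            raise FormatError("duplicate probe ids")
        if len(set(self.subject_ids)) != n_subjects:
            raise FormatError("duplicate subject ids")
        with np.errstate(invalid="ignore"):
            bad = ((self.beta < 0) | (self.beta > 1)) if self.check_range else np.zeros(1, bool)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {self.beta[i, j]!r} out of [0, 1] at probe "
                f"{self.probe_ids[i]!r}, subject {self.subject_ids[j]!r}"
            )
        self._subject_index = {s: k for k, s in enumerate(self.subject_ids)}
        self._probe_index = {p: k for k, p in enumerate(self.probe_ids)}

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.beta.shape[1]

    def subject_index(self, subject_id: str) -> int:
        try:
            return self._subject_index[subject_id]
        except KeyError:
            raise KeyError(f"unknown subject id {subject_id!r}") from None

    def probe_index(self, probe_id: str) -> int:
        try:
            return self._probe_index[probe_id]
        except KeyError:
            raise KeyError(f"unknown probe id {probe_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta, index=self.probe_ids, columns=self.subject_ids)


def read_beta_matrix(path, delimiter: str = "\t") -> MethylationMatrix:
    """Read a beta matrix: first column probe ids, header row subject ids.

    Empty fields and the tokens ``NA``/``NaN`` (any case) are missing values.
    Values outside [0, 1] raise :class:`ValidationError` naming the cell.
    """
    df = pd.read_csv(
        path,
        sep=delimiter,
        index_col=0,
        na_values=list(MISSING_TOKENS) + ["NA", "NaN", "NAN", "Na", "nA", "NaN"],
        keep_default_na=False,
        dtype=str,
    )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate probe id {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"duplicate subject id {dup!r} in {path}")
    # second missing-token pass, case-insensitive, then numeric parse
    values = df.to_numpy(dtype=object)
    mask_missing = np.zeros(values.shape, dtype=bool)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            v = values[i, j]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                mask_missing[i, j] = True
            elif isinstance(v, str) and v.strip().lower() in MISSING_TOKENS:
                mask_missing[i, j] = True
    beta = np.full(values.shape, np.nan)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            if mask_missing[i, j]:
                continue
            try:
                beta[i, j] = float(values[i, j])
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric beta {values[i, j]!r} at probe "
                    f"{df.index[i]!r}, subject {df.columns[j]!r}"
                ) from None
    return MethylationMatrix(
        probe_ids=df.index.to_numpy(dtype=object),
        subject_ids=[str(c) for c in df.columns],
        beta=beta,
    )


def write_beta_matrix(matrix: MethylationMatrix, path, delimiter: str = "\t") -> None:
    """Write a beta matrix; missing entries become ``NA``."""
    df = matrix.to_frame()
    df.index.name = "probe"
    df.to_csv(path, sep=delimiter, na_rep="NA", float_format="%.10g")


# ---------------------------------------------------------------------------
# Twin cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwinPair:
    pair_id: str
    subject_a: str
    subject_b: str
    age: float
    sex: str = ""


@dataclass
class TwinCohort:
    """A set of monozygotic twin pairs.

    Each subject belongs to exactly one pair, each unordered pair appears
    once, and both members share one age (MZ twins share a birth date).
    """

    pairs: list[TwinPair]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValidationError("cohort has no pairs")
        seen_subjects: dict[str, str] = {}
        seen_pairs: set[frozenset[str]] = set()
        seen_ids: set[str] = set()
        for p in self.pairs:
            if p.pair_id in seen_ids:
                raise ValidationError(f"duplicate pair id {p.pair_id!r}")
            seen_ids.add(p.pair_id)
            if p.subject_a == p.subject_b:
                raise ValidationError(f"pair {p.pair_id!r} lists one subject twice")
            key = frozenset((p.subject_a, p.subject_b))
            if key in seen_pairs:
                raise ValidationError(
                    f"pair {p.pair_id!r} duplicates an existing pair in the "
                    "opposite order; each unordered pair may appear once"
                )
            seen_pairs.add(key)
            for s in (p.subject_a, p.subject_b):
                if s in seen_subjects:
                    raise ValidationError(
                        f"subject {s!r} appears in pairs {seen_subjects[s]!r} "
                        f"and {p.pair_id!r}"
                    )
                seen_subjects[s] = p.pair_id
            if not np.isfinite(p.age) or p.age < 0:
                raise ValidationError(f"pair {p.pair_id!r} has invalid age {p.age!r}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def pair_ids(self) -> list[str]:
        return [p.pair_id for p in self.pairs]

    @property
    def ages(self) -> np.ndarray:
        return np.array([p.age for p in self.pairs], dtype=float)

    @property
    def subject_ids(self) -> list[str]:
        out: list[str] = []
        for p in self.pairs:
            out.extend((p.subject_a, p.subject_b))
        return out

    def pair(self, pair_id: str) -> TwinPair:
        for p in self.pairs:
            if p.pair_id == pair_id:
                return p
        raise KeyError(f"unknown pair id {pair_id!r}")


def read_pair_table(path, delimiter: str = "\t") -> TwinCohort:
    """Read a pair table with columns pair_id, subject_a, subject_b, age, sex.

    If separate per-subject ages are supplied (columns ``age_a``/``age_b``)
    and differ, the pair age is their mean and a warning is logged.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    required = {"pair_id", "subject_a", "subject_b"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"pair table must have columns {sorted(required)}; got {list(df.columns)}"
        )
    pairs = []
    for row in df.itertuples(index=False):
        if "age" in df.columns:
            age = float(getattr(row, "age"))
        elif {"age_a", "age_b"}.issubset(df.columns):
            aa, ab = float(getattr(row, "age_a")), float(getattr(row, "age_b"))
            if aa != ab:
                logger.warning(
                    "pair %s: per-subject ages differ (%s, %s); using their mean",
                    row.pair_id, aa, ab,
                )
            age = (aa + ab) / 2.0
        else:
            raise FormatError("pair table needs an 'age' (or 'age_a'/'age_b') column")
        sex = str(getattr(row, "sex", "")) if "sex" in df.columns else ""
        pairs.append(TwinPair(str(row.pair_id), str(row.subject_a),
                              str(row.subject_b), age, sex))
    return TwinCohort(pairs)


def write_pair_table(cohort: TwinCohort, path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in cohort.pairs],
            "subject_a": [p.subject_a for p in cohort.pairs],
            "subject_b": [p.subject_b for p in cohort.pairs],
            "age": [p.age for p in cohort.pairs],
            "sex": [p.sex for p in cohort.pairs],
        }
    )
    df.to_csv(path, sep=delimiter, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Probe annotation
# ---------------------------------------------------------------------------


@dataclass
class ProbeAnnotation:
    """Probe -> gene symbols and relation-to-CpG-island category.

    Probes absent from the annotation are gene-less with feature "Other".
    """

    genes: dict[str, frozenset[str]] = field(default_factory=dict)
    features: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for probe, feat in self.features.items():
            if feat not in CPG_FEATURES:
                raise ValidationError(
                    f"probe {probe!r} has unknown CpG feature {feat!r}; "
                    f"expected one of {CPG_FEATURES}"
                )

    def genes_of(self, probe: str) -> frozenset[str]:
        return self.genes.get(probe, frozenset())

    def feature_of(self, probe: str) -> str:
        return self.features.get(probe, "Other")

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for g in self.genes.values():
            out |= g
        return out


def map_relation_code(code: str) -> str:
    """Map an Illumina manifest relation-to-island code onto a category."""
    key = code.strip().lower()
    try:
        return RELATION_CODES[key]
    except KeyError:
        accepted = sorted({c for c in RELATION_CODES if c})
        raise ValidationError(
            f"unknown relation-to-island code {code!r}; accepted codes: {accepted}"
        ) from None


def read_annotation(path, delimiter: str = "\t") -> ProbeAnnotation:
    """Read an Illumina-manifest-style annotation.

    Expected columns (by name, else the first three columns in order):
    probe id, semicolon-separated gene symbols, relation-to-island code.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    probe_col = cols.get("probe") or cols.get("ilmnid") or cols.get("name") or df.columns[0]
    gene_col = cols.get("genes") or cols.get("ucsc_refgene_name") or df.columns[1]
    rel_col = (
        cols.get("relation_to_island")
        or cols.get("relation_to_ucsc_cpg_island")
        or df.columns[2]
    )
    genes: dict[str, frozenset[str]] = {}
    features: dict[str, str] = {}
    for probe, gene_str, rel in df[[probe_col, gene_col, rel_col]].itertuples(
        index=False, name=None
    ):
        probe = str(probe)
        symbols = frozenset(s.strip() for s in str(gene_str).split(";") if s.strip())
        genes[probe] = symbols
        features[probe] = map_relation_code(str(rel))
    return ProbeAnnotation(genes=genes, features=features)


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCatalog:
    """Named gene lists (elite genes, marker panels), deduplicated."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, symbols in self.sets.items():
            if any(not s for s in symbols):
                raise ValidationError(f"gene list {name!r} contains an empty symbol")

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return sorted(self.sets)


def read_gene_list(path) -> frozenset[str]:
    """Read a plain one-symbol-per-line gene list; blank lines and '#' comments skipped."""
    symbols = set()
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                symbols.add(s)
    return frozenset(symbols)


def read_gene_sets(paths: Mapping[str, object]) -> GeneSetCatalog:
    return GeneSetCatalog({name: read_gene_list(p) for name, p in paths.items()})


# ---------------------------------------------------------------------------
# Site-result table I/O
# ---------------------------------------------------------------------------


def write_site_results(results: pd.DataFrame, path, delimiter: str = "\t") -> None:
    """Write the per-site result table in the documented column order.

    SDs and EFI are printed to 6 significant digits, p and q in scientific
    notation; undefined values become ``NA``. Row order is preserved.
    """
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValidationError(f"result table is missing columns {missing}")
    out = results.loc[:, list(RESULT_COLUMNS)].copy()

    def fmt_g(x):
        return "NA" if pd.isna(x) else f"{x:.6g}"

    def fmt_e(x):
        return "NA" if pd.isna(x) else f"{x:.6e}"

    for col in ("sd_young", "sd_elderly", "efi"):
        out[col] = out[col].map(fmt_g)
    for col in ("p_levene", "q_storey"):
        out[col] = out[col].map(fmt_e)
    out.to_csv(path, sep=delimiter, index=False)


def read_site_results(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read back a site-result table written by :func:`write_site_results`."""
    df = pd.read_csv(path, sep=delimiter, na_values=["NA"], keep_default_na=False,
                     dtype={"probe": str, "class": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"result file {path} is missing columns {missing}")
    for col in ("n_valid_pairs_young", "n_valid_pairs_elderly"):
        df[col] = df[col].astype("Int64")
    return df
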