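"""Core domain types and file IO for pooled shRNA screens.

The pipeline revolves around four objects:

* :class:`ShRNALibrary` -- the hairpin reference: one row per hairpin with its
  guide sequence (the matcher key), target gene, pool assignment and class
  (``target`` or ``control``).
* :class:`SampleSheet` -- the experimental design: one row per sequenced
  sample with pool, timepoint (``t0``/``tF`` or free labels such as ``t7``),
  treatment and replicate.
* :class:`CountMatrix` -- integer hairpin x sample counts with per-sample
  library sizes derived as column sums.
* :class:`GeneSet` -- a named set of uppercase gene symbols (GMT files).

File dialects (the vendor library format is not public, so these are defined
here): the library TSV has columns ``hairpin_id, guide_seq, gene, pool,
class``; the library FASTA encodes ``hairpin_id|gene|pool`` in the header
with the guide as the sequence.  Counts are TSV with hairpins as rows
(first column ``hairpin_id``), matching the row-per-feature convention of
count-based differential analysis.  The sample sheet is CSV with columns
``sample_id, pool, timepoint, treatment, replicate``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError, ValidationError

DNA_ALPHABET = frozenset("ACGTN")

LIBRARY_COLUMNS = ["hairpin_id", "guide_seq", "gene", "pool", "class"]
SAMPLESHEET_COLUMNS = ["sample_id", "pool", "timepoint", "treatment", "replicate"]


def normalize_gene(symbol: str) -> str:
    """Canonical gene key: uppercase, whitespace stripped."""
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# ShRNALibrary
# ---------------------------------------------------------------------------


@dataclass
class ShRNALibrary:
    """Hairpin -> gene reference library.

    ``table`` has columns ``hairpin_id, guide_seq, gene, pool, class`` and is
    validated on construction: hairpin ids unique, guides drawn from
    {A,C,G,T,N} and all of the configured length.  Duplicate *guide*
    sequences are permitted (vendor libraries may contain them) but are
    reported by :meth:`duplicate_guides` rather than merged.
    """

    table: pd.DataFrame
    guide_length: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in LIBRARY_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"library is missing columns: {missing}")
        tab = self.table.loc[:, LIBRARY_COLUMNS].copy()
        tab["hairpin_id"] = tab["hairpin_id"].astype(str)
        tab["guide_seq"] = tab["guide_seq"].astype(str).str.upper()
        tab["gene"] = tab["gene"].map(normalize_gene)
        tab["pool"] = tab["pool"].astype(str)
        tab["class"] = tab["class"].astype(str)
        dup = tab["hairpin_id"].duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate hairpin_id(s): {sorted(tab.loc[dup, 'hairpin_id'])[:5]}"
            )
        bad_class = set(tab["class"]) - {"target", "control"}
        if bad_class:
            raise ValidationError(f"unknown hairpin class(es): {sorted(bad_class)}")
        lengths = tab["guide_seq"].str.len().unique()
        if len(lengths) > 1:
            raise ValidationError(f"guides have mixed lengths: {sorted(lengths)}")
        if self.guide_length is None:
            object.__setattr__(self, "guide_length", int(lengths[0]) if len(lengths) else 0)
        elif len(lengths) and int(lengths[0]) != self.guide_length:
            raise ValidationError(
                f"guide length {lengths[0]} != configured {self.guide_length}"
            )
        for seq in tab["guide_seq"]:
            if not set(seq) <= DNA_ALPHABET:
                raise ValidationError(f"non-DNA characters in guide {seq!r}")
        tab = tab.reset_index(drop=True)
        self.table = tab

    # -- properties ---------------------------------------------------------
    @property
    def n_hairpins(self) -> int:
        return len(self.table)

    @property
    def n_genes(self) -> int:
        return self.table["gene"].nunique()

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())

    @property
    def hairpin_ids(self) -> list[str]:
        return list(self.table["hairpin_id"])

    def gene_of(self) -> pd.Series:
        """hairpin_id -> gene mapping."""
        return self.table.set_index("hairpin_id")["gene"]

    def duplicate_guides(self) -> pd.DataFrame:
        """Rows whose guide sequence occurs more than once (reported, not merged)."""
        return self.table[self.table["guide_seq"].duplicated(keep=False)]

    # -- IO -----------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "ShRNALibrary":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "class" not in df.columns:
            df["class"] = "target"
        return cls(df)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ShRNALibrary":
        from Bio import SeqIO

        rows = []
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.id.split("|")
            if len(parts) != 3:
                raise FormatError(
                    f"FASTA header {rec.id!r} does not follow 'hairpin_id|gene|pool'"
                )
            rows.append(
                {
                    "hairpin_id": parts[0],
                    "guide_seq": str(rec.seq).upper(),
                    "gene": parts[1],
                    "pool": parts[2],
                    "class": "target",
                }
            )
        if not rows:
            raise FormatError(f"no FASTA records in {path}")
        return cls(pd.DataFrame(rows))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_library(path: str | Path, format: str | None = None) -> ShRNALibrary:
    """Read a hairpin library from TSV or FASTA (format inferred from suffix)."""
    if format is None:
        suffix = Path(path).suffix.lower()
        format = "fasta" if suffix in {".fa", ".fasta", ".fna"} else "tsv"
    if format == "fasta":
        return ShRNALibrary.from_fasta(path)
    if format == "tsv":
        return ShRNALibrary.from_tsv(path)
    raise FormatError(f"unknown library format {format!r}")


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------

_TIMEPOINT_RE = re.compile(r"^t(0|F|\d+)$")


@dataclass
class SampleSheet:
    """Experimental design table: sample_id, pool, timepoint, treatment, replicate."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLESHEET_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample sheet is missing columns: {missing}")
        tab = self.table.loc[:, SAMPLESHEET_COLUMNS].copy()
        for col in ("sample_id", "pool", "timepoint", "treatment"):
            tab[col] = tab[col].astype(str)
        tab["replicate"] = tab["replicate"].astype(int)
        if (tab["replicate"] < 1).any():
            raise ValidationError("replicate numbers must be positive integers")
        if tab["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample sheet")
        for tp in tab["timepoint"]:
            if not _TIMEPOINT_RE.match(tp):
                raise ValidationError(f"timepoint {tp!r} not of form t0/tF/t<n>")
        key = tab[["pool", "timepoint", "treatment", "replicate"]]
        if key.duplicated().any():
            raise ValidationError(
                "(pool, timepoint, treatment, replicate) combinations must be unique"
            )
        self.table = tab.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_where(self, **conditions) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        for col, val in conditions.items():
            mask &= self.table[col] == val
        return list(self.table.loc[mask, "sample_id"])

    def groups(self) -> pd.DataFrame:
        """Replicate counts per (pool, timepoint, treatment) group."""
        return (
            self.table.groupby(["pool", "timepoint", "treatment"])
            .size()
            .rename("n_replicates")
            .reset_index()
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer hairpin x sample count table.

    ``counts`` is indexed by hairpin_id with sample_id columns; values are
    validated to be non-negative integers.  ``lib_sizes`` is always derived
    (column sums), never user-set.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            raise ValidationError("duplicate hairpin rows in count matrix")
        if df.columns.duplicated().any():
            raise ValidationError("duplicate sample columns in count matrix")
        arr = df.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise FormatError("count matrix contains non-numeric cells")
            if np.any(arr < 0):
                raise FormatError("count matrix contains negative cells")
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("count matrix contains non-integer cells")
        self.counts = df.astype(np.int64)
        self.counts.index = self.counts.index.astype(str)
        self.counts.index.name = "hairpin_id"
        self.counts.columns = self.counts.columns.astype(str)

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def hairpin_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, samples: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(samples)].copy())

    def subset_hairpins(self, hairpins: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(hairpins)].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts)


def read_counts(path: str | Path) -> CountMatrix:
    """Read a hairpin x sample count TSV (first column ``hairpin_id``)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="hairpin_id")


# ---------------------------------------------------------------------------
# GeneSet / GMT
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    """A named set of uppercase-normalised gene symbols."""

    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        object.__setattr__(
            self, "genes", frozenset(normalize_gene(g) for g in self.genes)
        )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return normalize_gene(gene) in self.genes


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            sets.append(GeneSet(parts[0], frozenset(g for g in parts[2:] if g), parts[1]))
    if not sets:
        raise FormatError(f"no gene sets in {path}")
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.source, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Design validation
# ---------------------------------------------------------------------------


@dataclass
class DesignReport:
    """Outcome of cross-checking a CountMatrix against a SampleSheet."""

    groups: pd.DataFrame
    orphan_samples: list[str] = field(default_factory=list)
    missing_from_counts: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.warnings


def validate_design(cm: CountMatrix, ss: SampleSheet) -> DesignReport:
    """Check the design is analysable; raise :class:`DesignError` if fatal.

    Fatal: any tF treatment group in a pool without a matching t0 group in
    that pool.  Non-fatal (reported): count columns absent from the sheet,
    sheet samples absent from the counts.
    """
    tab = ss.table
    report = DesignReport(groups=ss.groups())
    for pool, sub in tab.groupby("pool"):
        has_t0 = (sub["timepoint"] == "t0").any()
        final_groups = sub.loc[sub["timepoint"] != "t0", "treatment"].unique()
        if len(final_groups) and not has_t0:
            raise DesignError(
                f"pool {pool!r} has final-timepoint group(s) "
                f"{sorted(final_groups)} but no t0 samples"
            )
    orphans = sorted(set(cm.sample_ids) - set(ss.sample_ids))
    if orphans:
        report.orphan_samples = orphans
        report.warnings.append(f"count columns not in sample sheet: {orphans}")
    missing = sorted(set(ss.sample_ids) - set(cm.sample_ids))
    if missing:
        report.missing_from_counts = missing
        report.warnings.append(f"sheet samples absent from counts: {missing}")
    return report
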