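"""Hairpin quantification from raw reads.

Raw barcode reads are turned into a :class:`~dropscreen.screen_model.CountMatrix`
by a deterministic, dictionary-based matcher: reads are trimmed to the guide
length, quality-trimmed from the 3' end (Phred+33), and looked up against
the library's guide set either exactly or allowing a single mismatch.  Since
the reference is a fixed set of equal-length k-mers, hashing makes counting
bit-reproducible with no positional-alignment dependency.

In ``one_mismatch`` mode a read is counted iff exactly one library guide
attains the minimal Hamming distance (0 or 1); reads with two or more
guides at the minimal distance are discarded as ambiguous and reported in
:class:`QuantStats`.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DropscreenError, FormatError, ValidationError
from .screen_model import CountMatrix, ShRNALibrary

Read = tuple[str, str, str]  # (id, sequence, quality)

PHRED_OFFSET = 33


@dataclass
class QuantStats:
    """Per-sample quantification accounting."""

    total_reads: int = 0
    dropped_short: int = 0
    reads_after_qc: int = 0
    matched_reads: int = 0
    ambiguous_reads: int = 0
    hairpins_detected: int = 0
    library_size: int = 0  # H, for fraction_reference_detected

    @property
    def match_rate(self) -> float:
        return self.matched_reads / self.reads_after_qc if self.reads_after_qc else 0.0

    @property
    def fraction_reference_detected(self) -> float:
        return self.hairpins_detected / self.library_size if self.library_size else 0.0


# ---------------------------------------------------------------------------
# FASTQ streaming
# ---------------------------------------------------------------------------


def open_fastq(path: str | Path) -> Iterator[Read]:
    """Stream (id, seq, qual) records from a FASTQ or FASTQ.gz file."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        try:
            for rec in FastqGeneralIterator(fh):
                yield rec
        except ValueError as exc:  # malformed record
            raise FormatError(f"{path}: {exc}") from exc


def trim_reads(
    reads: Iterable[Read], length: int = 22, stats: QuantStats | None = None
) -> Iterator[Read]:
    """Trim every read (and its qualities, in lockstep) to ``length`` bases.

    Reads shorter than ``length`` are dropped and counted in ``stats``.
    """
    for rid, seq, qual in reads:
        if stats is not None:
            stats.total_reads += 1
        if len(seq) < length:
            if stats is not None:
                stats.dropped_short += 1
            continue
        yield rid, seq[:length], qual[:length]


def quality_filter(
    reads: Iterable[Read],
    min_q: int = 20,
    min_len: int = 22,
    stats: QuantStats | None = None,
) -> Iterator[Read]:
    """Remove trailing 3' bases with quality below ``min_q`` (Phred+33).

    Reads left shorter than ``min_len`` are dropped and counted.  Quality
    characters below the encoding floor ('!') raise a format error.
    """
    for rid, seq, qual in reads:
        scores = [ord(c) - PHRED_OFFSET for c in qual]
        if any(s < 0 for s in scores):
            raise FormatError(f"read {rid!r}: quality below Phred+33 encoding floor")
        end = len(scores)
        while end > 0 and scores[end - 1] < min_q:
            end -= 1
        if end < min_len:
            if stats is not None:
                stats.dropped_short += 1
            continue
        yield rid, seq[:end], qual[:end]


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


def _guide_index(lib: ShRNALibrary) -> dict[str, list[str]]:
    index: dict[str, list[str]] = {}
    for hid, guide in zip(lib.table["hairpin_id"], lib.table["guide_seq"]):
        index.setdefault(guide, []).append(hid)
    return index


def _neighbours(seq: str) -> Iterator[str]:
    """All sequences at Hamming distance exactly 1."""
    for i, cur in enumerate(seq):
        for base in "ACGT":
            if base != cur:
                yield seq[:i] + base + seq[i + 1 :]


def match_hairpins(
    reads: Iterable[Read],
    lib: ShRNALibrary,
    mode: str = "exact",
    stats: QuantStats | None = None,
) -> tuple[dict[str, int], QuantStats]:
    """Count reads per hairpin by exact or single-mismatch dictionary lookup."""
    if mode not in {"exact", "one_mismatch"}:
        raise DropscreenError(f"unknown matching mode {mode!r}")
    if stats is None:
        stats = QuantStats()
    stats.library_size = lib.n_hairpins
    index = _guide_index(lib)
    L = lib.guide_length
    counts: dict[str, int] = {hid: 0 for hid in lib.hairpin_ids}
    for rid, seq, _qual in reads:
        if len(seq) != L:
            raise DropscreenError(
                f"read {rid!r} has length {len(seq)} != guide length {L}"
            )
        stats.reads_after_qc += 1
        hits = index.get(seq)
        if hits is None and mode == "one_mismatch":
            found: list[str] = []
            for nb in _neighbours(seq):
                found.extend(index.get(nb, ()))
            hits = found or None
        if hits is None:
            continue
        if len(hits) == 1:
            counts[hits[0]] += 1
            stats.matched_reads += 1
        else:
            stats.ambiguous_reads += 1
    stats.hairpins_detected = sum(1 for v in counts.values() if v > 0)
    return counts, stats


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def quantify(
    fastq_by_sample: Mapping[str, str | Path | Sequence[str | Path]],
    lib: ShRNALibrary,
    mode: str = "exact",
    min_q: int = 20,
    quality_trim: bool = True,
) -> tuple[CountMatrix, dict[str, QuantStats]]:
    """FASTQ -> CountMatrix: trim to guide length, 3' quality filter, match.

    ``fastq_by_sample`` maps sample ids to one path or a sequence of paths.
    Hairpins never observed keep a zero row; a sample with no surviving
    reads produces an all-zero column with a warning.
    """
    L = lib.guide_length
    columns: dict[str, dict[str, int]] = {}
    all_stats: dict[str, QuantStats] = {}
    for sample, paths in fastq_by_sample.items():
        if isinstance(paths, (str, Path)):
            paths = [paths]
        stats = QuantStats()

        def stream() -> Iterator[Read]:
            for p in paths:
                yield from open_fastq(p)

        reads: Iterable[Read] = trim_reads(stream(), length=L, stats=stats)
        if quality_trim:
            reads = quality_filter(reads, min_q=min_q, min_len=L, stats=stats)
        counts, stats = match_hairpins(reads, lib, mode=mode, stats=stats)
        if stats.reads_after_qc == 0:
            warnings.warn(f"sample {sample!r}: no reads survived QC", stacklevel=2)
        columns[sample] = counts
        all_stats[sample] = stats
    cm = CountMatrix(
        pd.DataFrame(columns, index=pd.Index(lib.hairpin_ids, name="hairpin_id")).fillna(0)
    )
    return cm, all_stats


def stats_frame(stats: Mapping[str, QuantStats]) -> pd.DataFrame:
    """Tabulate per-sample QuantStats (for the JSON/TSV report)."""
    rows = []
    for sample, st in stats.items():
        rows.append(
            {
                "sample_id": sample,
                "total_reads": st.total_reads,
                "dropped_short": st.dropped_short,
                "reads_after_qc": st.reads_after_qc,
                "matched_reads": st.matched_reads,
                "ambiguous_reads": st.ambiguous_reads,
                "match_rate": st.match_rate,
                "hairpins_detected": st.hairpins_detected,
                "fraction_reference_detected": st.fraction_reference_detected,
            }
        )
    return pd.DataFrame(rows)
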