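"""Alignment ingestion, QC read filters and chimeric-pair extraction.

A NUMT-supporting ("chimeric") read pair has one mate mapped to the
mitochondrial contig and the other to a nuclear chromosome.  Because the
integration breakpoint itself is not resolved, the nuclear-side mate's
leftmost mapped coordinate serves as the insertion-site proxy; typical
mate separation in the libraries this targets is short (~150 bp), so the
proxy is accurate to a few hundred bases.

Pairs are reconstructed from either mate's record via the SAM mate fields,
so a chimeric pair is detected even when only one of its records survives
filtering; duplicates by ``query_name`` are collapsed.  All coordinates are
converted to 0-based on ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .genome_model import (
    DEFAULT_MITO_NAMES,
    GenomeBuild,
    IntervalPartition,
    PartitionError,
)

logger = logging.getLogger(__name__)

# SAM flag bits
FPAIRED = 0x1
FPROPER = 0x2
FUNMAP = 0x4
FMUNMAP = 0x8
FREVERSE = 0x10
FMREVERSE = 0x20
FREAD1 = 0x40
FREAD2 = 0x80
FSECONDARY = 0x100
FQCFAIL = 0x200
FDUP = 0x400
FSUPPLEMENTARY = 0x800


class MitoContigError(ValueError):
    """None of the configured mitochondrial contig names is in the header."""


class CountInconsistencyError(ValueError):
    """NUMT pairs observed in an interval with zero mapped reads."""


@dataclass(frozen=True)
class ReadRecord:
    """One primary-or-otherwise alignment record; ``pos`` is 0-based."""

    query_name: str
    contig: str | None
    pos: int
    mate_contig: str | None
    mate_pos: int
    mapq: int
    flag: int

    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FPAIRED)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FUNMAP)

    @property
    def mate_is_unmapped(self) -> bool:
        return bool(self.flag & FMUNMAP)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FDUP)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FSECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FSUPPLEMENTARY)


@dataclass(frozen=True)
class NumtPair:
    """One mito-nuclear chimeric read pair (one insertion observation)."""

    sample_id: str
    genome_type: str  # 't' or 'h'
    nuclear_contig: str
    nuclear_pos: int
    mito_pos: int
    min_mapq: int


PAIR_COLUMNS = [
    "sample_id",
    "genome_type",
    "nuclear_contig",
    "nuclear_pos",
    "mito_pos",
    "min_mapq",
]


def pairs_to_frame(pairs: Iterable[NumtPair]) -> pd.DataFrame:
    rows = [
        (p.sample_id, p.genome_type, p.nuclear_contig, p.nuclear_pos, p.mito_pos,
         p.min_mapq)
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def frame_to_pairs(df: pd.DataFrame) -> list[NumtPair]:
    return [
        NumtPair(r.sample_id, r.genome_type, r.nuclear_contig, int(r.nuclear_pos),
                 int(r.mito_pos), int(r.min_mapq))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# ingestion


def read_alignments(path, region: str | None = None) -> Iterator[ReadRecord]:
    """Stream records from a SAM/BAM file in file order.

    ``region`` (samtools-style string) requires a coordinate-sorted, indexed
    file.  Flags are passed through; 1-based SAM positions become 0-based.
    """
    import pysam

    af = pysam.AlignmentFile(str(path), check_sq=False)
    try:
        it = af.fetch(region=region) if region else af.fetch(until_eof=True)
        for rec in it:
            yield ReadRecord(
                query_name=rec.query_name,
                contig=rec.reference_name,
                pos=rec.reference_start if rec.reference_start is not None else -1,
                mate_contig=rec.next_reference_name,
                mate_pos=(
                    rec.next_reference_start
                    if rec.next_reference_start is not None
                    else -1
                ),
                mapq=rec.mapping_quality,
                flag=rec.flag,
            )
    finally:
        af.close()


def filter_reads(
    stream: Iterable[ReadRecord],
    drop_duplicates: bool = True,
    drop_secondary_supplementary: bool = True,
    min_mapq: int = 0,
) -> Iterator[ReadRecord]:
    """QC filter: drop duplicate-flagged, secondary/supplementary and
    low-MAPQ records.  Pure, order-preserving, idempotent."""
    for rec in stream:
        if drop_duplicates and rec.is_duplicate:
            continue
        if drop_secondary_supplementary and (rec.is_secondary or rec.is_supplementary):
            continue
        if rec.mapq < min_mapq:
            continue
        yield rec


def mark_duplicates(records: Sequence[ReadRecord]) -> list[ReadRecord]:
    """Internal duplicate marker for inputs without duplicate flags.

    Every record after the first sharing a (contig, pos, mate_contig,
    mate_pos) signature gets the duplicate flag set.  The input flag, when
    already set, is kept.
    """
    seen: set[tuple] = set()
    out = []
    for rec in records:
        sig = (rec.contig, rec.pos, rec.mate_contig, rec.mate_pos,
               rec.flag & (FREAD1 | FREAD2))
        if sig in seen:
            out.append(replace(rec, flag=rec.flag | FDUP))
        else:
            seen.add(sig)
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# chimeric-pair extraction


def extract_numt_pairs(
    stream: Iterable[ReadRecord],
    mito_names: frozenset[str] | set[str] = DEFAULT_MITO_NAMES,
    sample_id: str = "",
    genome_type: str = "t",
    contigs: Iterable[str] | None = None,
) -> list[NumtPair]:
    """Extract mito-nuclear chimeric pairs from a (filtered) record stream.

    One :class:`NumtPair` is produced per read pair in which exactly one
    mate's contig is mitochondrial.  The pair is reconstructed from either
    mate via the mate fields and deduplicated by ``query_name``; when both
    mates are seen, ``min_mapq`` is the minimum of the two mapping
    qualities, otherwise the single observed record's MAPQ.

    ``contigs``, when given (e.g. the header's reference names), validates
    that at least one configured mito name exists.
    """
    mito_names = frozenset(mito_names)
    if contigs is not None:
        contigs = list(contigs)
        if not mito_names & set(contigs):
            raise MitoContigError(
                f"none of the mito contig names {sorted(mito_names)} found; "
                f"header contigs: {contigs}"
            )
    found: dict[str, NumtPair] = {}
    for rec in stream:
        if rec.is_unmapped or rec.mate_is_unmapped or not rec.is_paired:
            continue
        if rec.contig is None or rec.mate_contig is None:
            continue
        self_mito = rec.contig in mito_names
        mate_mito = rec.mate_contig in mito_names
        if self_mito == mate_mito:  # both mito or both nuclear
            continue
        if self_mito:
            nuclear_contig, nuclear_pos = rec.mate_contig, rec.mate_pos
            mito_pos = rec.pos
        else:
            nuclear_contig, nuclear_pos = rec.contig, rec.pos
            mito_pos = rec.mate_pos
        prev = found.get(rec.query_name)
        if prev is None:
            found[rec.query_name] = NumtPair(
                sample_id, genome_type, nuclear_contig, nuclear_pos, mito_pos,
                rec.mapq,
            )
        else:
            # second mate of an already-seen pair: only MAPQ can improve info
            found[rec.query_name] = replace(
                prev, min_mapq=min(prev.min_mapq, rec.mapq)
            )
    return list(found.values())


# ---------------------------------------------------------------------------
# counting


def count_mapped_reads(
    stream: Iterable[ReadRecord], partition: IntervalPartition
) -> dict[str, int]:
    """Count retained mapped reads per interval by leftmost coordinate.

    Reads on contigs absent from the partition contribute nowhere, so the
    total over intervals is <= the number of retained reads.
    """
    contigs: list[str] = []
    positions: list[int] = []
    for rec in stream:
        if rec.is_unmapped or rec.contig is None:
            continue
        contigs.append(rec.contig)
        positions.append(rec.pos)
    if not contigs:
        return {iid: 0 for iid in partition.ids}
    return partition.count(contigs, positions)


def count_mapped_reads_by_contig(stream: Iterable[ReadRecord]) -> dict[str, int]:
    """Mapped-read tally per contig (feeds genome-level normalization)."""
    counts: dict[str, int] = {}
    for rec in stream:
        if rec.is_unmapped or rec.contig is None:
            continue
        counts[rec.contig] = counts.get(rec.contig, 0) + 1
    return counts


MITO_LEVELS = frozenset({"mtg", "mst", "mgn"})

COUNT_COLUMNS = ["sample_id", "genome_type", "interval_id", "numt_count",
                 "mapped_count"]


def build_sample_counts(
    numt_pairs: Sequence[NumtPair] | pd.DataFrame,
    mapped_counts: dict[str, int],
    partition: IntervalPartition,
    sample_id: str,
    genome_type: str,
    build: GenomeBuild | None = None,
) -> pd.DataFrame:
    """Assemble the per-interval (N, M) table for one sample.

    N is the chimeric-pair count whose nuclear proxy (nuclear levels) or
    mito breakpoint (mito levels) falls in the interval; M comes from
    ``mapped_counts``.  At the ``gen`` level ``mapped_counts`` must be a
    per-contig tally and ``build`` must be given: M excludes
    sex-chromosome reads while N keeps pairs landing there.
    """
    df = numt_pairs if isinstance(numt_pairs, pd.DataFrame) else pairs_to_frame(
        numt_pairs
    )
    if partition.level in MITO_LEVELS:
        if len(df) and df["nuclear_contig"].isin(partition.contigs).any():
            raise PartitionError(
                "mito-level partition given nuclear-side coordinates"
            )
        contig = next(iter(partition.contigs)) if len(partition.contigs) else "chrM"
        point_contigs = [contig] * len(df)
        point_pos = df["mito_pos"].tolist()
    else:
        point_contigs = df["nuclear_contig"].tolist()
        point_pos = df["nuclear_pos"].tolist()

    if partition.level == "gen":
        if build is None:
            raise PartitionError("gen-level counting requires a GenomeBuild")
        n_gen = sum(
            1 for c in point_contigs if c in build.nuclear_contigs
        )
        m_gen = sum(mapped_counts.get(c, 0) for c in build.autosomes)
        rows = [(sample_id, genome_type, "gen", n_gen, m_gen)]
        return pd.DataFrame(rows, columns=COUNT_COLUMNS)

    n_counts = partition.count(point_contigs, point_pos)
    rows = [
        (sample_id, genome_type, iid, n_counts.get(iid, 0),
         int(mapped_counts.get(iid, 0)))
        for iid in partition.ids
    ]
    out = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    bad = out[(out.mapped_count == 0) & (out.numt_count > 0)]
    if len(bad):
        logger.warning(
            "%d intervals with NUMT pairs but zero mapped reads (sample %s)",
            len(bad), sample_id,
        )
    return out


def write_pairs_tsv(pairs: Sequence[NumtPair] | pd.DataFrame, path) -> None:
    df = pairs if isinstance(pairs, pd.DataFrame) else pairs_to_frame(pairs)
    df.to_csv(path, sep="\t", index=False)


def write_pairs_bed(
    pairs: Sequence[NumtPair] | pd.DataFrame, path, pad: int = 0
) -> None:
    """Nuclear insertion proxies as BED (0-based half-open, +/- pad)."""
    df = pairs if isinstance(pairs, pd.DataFrame) else pairs_to_frame(pairs)
    with open(path, "w") as fh:
        for r in df.itertuples(index=False):
            start = max(0, int(r.nuclear_pos) - pad)
            end = int(r.nuclear_pos) + 1 + pad
            fh.write(
                f"{r.nuclear_contig}\t{start}\t{end}\t"
                f"{r.sample_id}:{r.genome_type}:mito{int(r.mito_pos)}\t"
                f"{int(r.min_mapq)}\t.\n"
            )
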