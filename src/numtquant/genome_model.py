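"""Genomic partitions used to bin NUMT evidence.

The pipeline quantifies NUMT abundance over five nested nuclear partitions —
whole genome (``gen``), chromosome (``chr``), chromosome arm (``arm``),
cytoband (``cyt``) and sliding window (``win``) — and three mitochondrial
partitions: whole mito genome (``mtg``), replication strand (``mst``) and
gene (``mgn``).

All coordinates are stored 0-based half-open.  SAM input (1-based) is
converted on ingest by :mod:`numtquant.alignment_io`; BED/TSV output keeps
the 0-based half-open convention.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

LEVELS = ("gen", "chr", "arm", "cyt", "win", "mtg", "mst", "mgn")

#: every stain value a UCSC cytoBand table may carry
GIEMSA_STAINS = frozenset(
    {"gneg", "gpos25", "gpos50", "gpos75", "gpos100", "acen", "gvar", "stalk"}
)
#: the five groups used in stain-stratified summaries (acen/gvar/stalk excluded)
GIEMSA_GROUPS = ("gneg", "gpos25", "gpos50", "gpos75", "gpos100")

DEFAULT_MITO_NAMES = frozenset({"chrM", "MT", "chrMT"})

#: id of the catch-all bin for breakpoints outside every annotated interval
UNANNOTATED = "unannotated"


class PartitionError(ValueError):
    """Malformed partition definition or level/coordinate-space mismatch."""


class AnnotationParseError(ValueError):
    """Malformed annotation input; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class Interval:
    """One partition interval, 0-based half-open.

    Several intervals may share an ``id``: a wrapped mitochondrial interval
    (the d-loop crossing the origin of the circular genome) is stored as two
    arcs with one shared id, and counting treats them as a single bin.
    """

    id: str
    contig: str
    start: int
    end: int
    attrs: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise PartitionError(
                f"interval {self.id}: bad coordinates [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos < self.end


@dataclass(frozen=True)
class GenomeBuild:
    """Contig names and lengths plus the sex/mito conventions of a build."""

    contigs: Mapping[str, int]
    sex_chromosomes: frozenset[str] = frozenset({"chrX", "chrY"})
    mito_name: str = "chrM"

    @property
    def nuclear_contigs(self) -> tuple[str, ...]:
        return tuple(c for c in self.contigs if c != self.mito_name)

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(
            c
            for c in self.contigs
            if c != self.mito_name and c not in self.sex_chromosomes
        )

    @property
    def mito_length(self) -> int:
        return self.contigs[self.mito_name]

    @classmethod
    def from_fasta(
        cls,
        fasta_path,
        sex_chromosomes: Iterable[str] = ("chrX", "chrY"),
        mito_name: str = "chrM",
    ) -> "GenomeBuild":
        from pyfaidx import Fasta

        fa = Fasta(str(fasta_path))
        contigs = {name: len(fa[name]) for name in fa.keys()}
        fa.close()
        return cls(contigs, frozenset(sex_chromosomes), mito_name)

    @classmethod
    def from_alignment(
        cls,
        path,
        sex_chromosomes: Iterable[str] = ("chrX", "chrY"),
        mito_name: str = "chrM",
    ) -> "GenomeBuild":
        import pysam

        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            contigs = dict(zip(af.references, af.lengths))
        return cls(contigs, frozenset(sex_chromosomes), mito_name)


class IntervalPartition:
    """A named partition level with its ordered intervals.

    Within one level, intervals on a contig must be non-overlapping unless
    the partition is an overlapping sliding-window grid (``step < size``),
    in which case counting treats each window independently.
    """

    def __init__(
        self,
        level: str,
        intervals: Sequence[Interval],
        overlapping: bool = False,
    ):
        if level not in LEVELS:
            raise PartitionError(f"unknown partition level {level!r}")
        self.level = level
        self.intervals = list(intervals)
        self.overlapping = overlapping
        self._index: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        if not overlapping:
            self._validate_disjoint()
        self._build_index()

    def _validate_disjoint(self):
        by_contig: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            by_contig.setdefault(iv.contig, []).append(iv)
        for contig, ivs in by_contig.items():
            ivs = sorted(ivs, key=lambda i: i.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise PartitionError(
                        f"level {self.level}: overlapping intervals on {contig}: "
                        f"{a.id} and {b.id}"
                    )

    def _build_index(self):
        if self.overlapping:
            return
        by_contig: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            by_contig.setdefault(iv.contig, []).append(iv)
        for contig, ivs in by_contig.items():
            ivs = sorted(ivs, key=lambda i: i.start)
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            ids = [iv.id for iv in ivs]
            self._index[contig] = (starts, ends, ids)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    @property
    def ids(self) -> list[str]:
        """Interval ids in genomic order, deduplicated (multi-arc ids once)."""
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.id, None)
        return list(seen)

    @property
    def contigs(self) -> frozenset[str]:
        return frozenset(iv.contig for iv in self.intervals)

    def assign(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Map 0-based positions on ``contig`` to interval ids.

        Returns an object array of ids; positions outside every interval get
        ``None``.  Requires a non-overlapping partition; for overlapping
        windows use :meth:`windows_containing`.
        """
        if self.overlapping:
            raise PartitionError("assign() undefined for overlapping windows")
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.shape, None, dtype=object)
        entry = self._index.get(contig)
        if entry is None:
            return out
        starts, ends, ids = entry
        k = np.searchsorted(starts, positions, side="right") - 1
        ok = (k >= 0) & (positions < ends[np.clip(k, 0, len(ends) - 1)])
        for i in np.nonzero(ok)[0]:
            out[i] = ids[k[i]]
        return out

    def windows_containing(self, contig: str, pos: int) -> list[str]:
        """All interval ids containing a position (overlapping grids)."""
        return [iv.id for iv in self.intervals if iv.contains(contig, pos)]

    def count(self, contigs: Sequence[str], positions: Sequence[int]) -> dict[str, int]:
        """Count how many (contig, pos) points fall in each interval.

        Every interval id appears in the result, zero-filled.  For
        overlapping windows a point increments every window containing it.
        """
        counts = {iid: 0 for iid in self.ids}
        contigs = np.asarray(contigs, dtype=object)
        positions = np.asarray(positions, dtype=np.int64)
        if self.overlapping:
            by_contig: dict[str, np.ndarray] = {}
            for c in np.unique(contigs):
                by_contig[c] = np.sort(positions[contigs == c])
            for iv in self.intervals:
                pos = by_contig.get(iv.contig)
                if pos is None:
                    continue
                lo = np.searchsorted(pos, iv.start, side="left")
                hi = np.searchsorted(pos, iv.end, side="left")
                counts[iv.id] += int(hi - lo)
            return counts
        for c in np.unique(contigs):
            mask = contigs == c
            ids = self.assign(c, positions[mask])
            for iid in ids:
                if iid is not None:
                    counts[iid] += 1
        return counts

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                attrs = iv.attrs.get("strand", ".")
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t{attrs}\n")


# ---------------------------------------------------------------------------
# partition constructors


def make_genome_partition(build: GenomeBuild) -> IntervalPartition:
    """``gen`` level: one shared-id interval per nuclear contig.

    N at this level counts chimeric pairs on every nuclear contig (sex
    chromosomes included); the sex-chromosome exclusion applies to the
    mapped-read denominator only and is handled at counting time.
    """
    ivs = [Interval("gen", c, 0, build.contigs[c]) for c in build.nuclear_contigs]
    return IntervalPartition("gen", ivs)


def make_chromosome_partition(build: GenomeBuild) -> IntervalPartition:
    ivs = [Interval(c, c, 0, build.contigs[c]) for c in build.nuclear_contigs]
    return IntervalPartition("chr", ivs)


def build_windows(
    build: GenomeBuild, size: int = 2_500_000, step: int | None = None
) -> IntervalPartition:
    """Sliding-window (``win``) partition over the nuclear chromosomes.

    Default step equals size, i.e. disjoint tiling, so window counts sum to
    chromosome counts; ``step < size`` yields overlapping windows counted
    independently.  Windows are clipped at the chromosome end; ids are
    ``"contig:start-end"`` in 0-based half-open coordinates.
    """
    if size <= 0:
        raise PartitionError(f"window size must be positive, got {size}")
    step = size if step is None else step
    if step <= 0 or step > size:
        raise PartitionError(f"window step must satisfy 0 < step <= size, got {step}")
    ivs = []
    for contig in build.nuclear_contigs:
        length = build.contigs[contig]
        k = 0
        while k * step < length:
            start = k * step
            end = min(start + size, length)
            ivs.append(Interval(f"{contig}:{start}-{end}", contig, start, end))
            k += 1
    return IntervalPartition("win", ivs, overlapping=step < size)


def load_cytobands(path) -> IntervalPartition:
    """Read a UCSC-style cytoBand table (chrom, start, end, band, stain).

    Input coordinates are 0-based half-open and preserved; the stain value
    is kept as an interval attribute.
    """
    ivs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise AnnotationParseError(
                    f"expected 5 tab-separated fields, got {len(parts)}", lineno
                )
            chrom, start, end, band, stain = parts[:5]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise AnnotationParseError(
                    f"non-integer coordinates {start!r}/{end!r}", lineno
                ) from None
            if stain not in GIEMSA_STAINS:
                raise AnnotationParseError(f"unknown Giemsa stain {stain!r}", lineno)
            ivs.append(
                Interval(f"{chrom}{band}", chrom, start_i, end_i, {"stain": stain,
                                                                   "band": band})
            )
    return IntervalPartition("cyt", ivs)


def derive_arms(cyt: IntervalPartition) -> IntervalPartition:
    """Chromosome arms from cytoband names (p/q prefix).

    Arm p spans [min start, max end) of the p-bands of a chromosome,
    likewise q; acrocentric chromosomes (one prefix only) yield one arm.
    Centromeric (acen) bands belong to the arm their prefix names.
    """
    spans: dict[tuple[str, str], list[int]] = {}
    for iv in cyt:
        band = str(iv.attrs.get("band", iv.id[len(iv.contig):]))
        if not band or band[0] not in "pq":
            raise AnnotationParseError(
                f"band name {band!r} on {iv.contig} lacks a p/q prefix"
            )
        key = (iv.contig, band[0])
        if key in spans:
            spans[key][0] = min(spans[key][0], iv.start)
            spans[key][1] = max(spans[key][1], iv.end)
        else:
            spans[key] = [iv.start, iv.end]
    ivs = [
        Interval(f"{contig}{arm}", contig, start, end)
        for (contig, arm), (start, end) in spans.items()
    ]
    ivs.sort(key=lambda iv: (iv.contig, iv.start))
    return IntervalPartition("arm", ivs)


def load_mito_annotation(
    path,
    mito_length: int,
    mito_name: str = "chrM",
    heavy_strand: str = "+",
) -> tuple[IntervalPartition, IntervalPartition, IntervalPartition]:
    """Read a BED6 mitochondrial gene table into the three mito partitions.

    Returns ``(mgn, mst, mtg)``: per-gene intervals, the heavy/light strand
    grouping (strand mapped via ``heavy_strand``), and the whole-genome
    partition.  A record whose name repeats is treated as a second arc of
    the same wrapped interval (circular genome; e.g. the d-loop crossing
    the origin).
    """
    gene_ivs: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise AnnotationParseError(
                    f"expected BED6 (6 fields), got {len(parts)}", lineno
                )
            chrom, start, end, name, _score, strand = parts[:6]
            start_i, end_i = int(start), int(end)
            if end_i > mito_length:
                raise AnnotationParseError(
                    f"interval {name} end {end_i} exceeds mito length {mito_length}",
                    lineno,
                )
            gene_ivs.append(
                Interval(name, mito_name if chrom else mito_name, start_i, end_i,
                         {"strand": strand})
            )
    mgn = IntervalPartition("mgn", gene_ivs)
    strand_ivs = [
        Interval(
            "heavy" if iv.attrs["strand"] == heavy_strand else "light",
            iv.contig,
            iv.start,
            iv.end,
            {"strand": iv.attrs["strand"]},
        )
        for iv in gene_ivs
    ]
    mst = IntervalPartition("mst", strand_ivs)
    mtg = IntervalPartition("mtg", [Interval("mtg", mito_name, 0, mito_length)])
    return mgn, mst, mtg


def default_mito_annotation(
    mito_length: int = 16_569, mito_name: str = "chrM"
) -> tuple[IntervalPartition, IntervalPartition, IntervalPartition]:
    """The bundled human-mtDNA-style gene table (13 protein genes, 2 rRNAs,
    d-loop) as partitions; see ``data/mito_genes.bed`` for provenance."""
    ref = importlib.resources.files("numtquant.data") / "mito_genes.bed"
    with importlib.resources.as_file(ref) as p:
        return load_mito_annotation(p, mito_length, mito_name)


# ---------------------------------------------------------------------------
# GC content


def gc_per_interval(fasta_path, partition: IntervalPartition) -> dict[str, float]:
    """GC fraction per interval id: (G+C) / (A+C+G+T), case-insensitive.

    Ambiguity codes (N etc.) are excluded from the denominator; an interval
    with zero unambiguous bases is omitted from the result.  Arcs sharing an
    id are aggregated before the ratio is taken.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    missing = partition.contigs - set(fa.keys())
    if missing:
        fa.close()
        raise KeyError(f"contigs absent from FASTA: {sorted(missing)}")
    gc_counts: dict[str, int] = {}
    acgt_counts: dict[str, int] = {}
    for iv in partition:
        seq = str(fa[iv.contig][iv.start : iv.end]).upper()
        gc = seq.count("G") + seq.count("C")
        acgt = gc + seq.count("A") + seq.count("T")
        gc_counts[iv.id] = gc_counts.get(iv.id, 0) + gc
        acgt_counts[iv.id] = acgt_counts.get(iv.id, 0) + acgt
    fa.close()
    return {
        iid: gc_counts[iid] / acgt_counts[iid]
        for iid in gc_counts
        if acgt_counts[iid] > 0
    }
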