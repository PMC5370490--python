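"""Synthetic matched tumor/normal cohorts with implanted chimeric pairs.

The generator emulates the statistical structure the analysis assumes:
paired-end alignments with short (~150 bp) mate separation, a
duplicate-flagged fraction, background concordant pairs, and mito-nuclear
chimeric pairs implanted at a healthy baseline rate and an elevated tumor
rate.  mtDNA-side breakpoints come from a hotspot mixture over the
bundled mitochondrial gene table (uniform remainder); nuclear landing
windows are optionally GC-biased (weight proportional to exp(beta * GC)).

Two fidelities share one truth model:

* :func:`write_cohort` emits a complete self-contained workspace — one
  SAM per sample, FASTA (+ .fai), cytoband TSV, mito gene BED, metadata
  TSV and truth TSV — for end-to-end pipeline tests.
* :func:`simulate_counts` skips read records and returns the chimeric
  pair table plus multinomially allocated background read counts on a
  fine window grid, for cohort-scale statistical experiments where file
  I/O would dominate.

Every sample draws from its own RNG substream derived from the root seed
and a stable hash of the sample id, so changing the cohort composition
does not reshuffle other samples.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome_model import (
    GenomeBuild,
    Interval,
    IntervalPartition,
    default_mito_annotation,
)

DEFAULT_CONTIGS = {
    "chr1": 5_000_000,
    "chr2": 4_000_000,
    "chr3": 3_500_000,
    "chrX": 2_000_000,
    "chrM": 16_569,
}

TRUTH_COLUMNS = [
    "participant",
    "sample_id",
    "genome_type",
    "query_name",
    "nuclear_contig",
    "nuclear_pos",
    "mito_pos",
    "is_duplicate",
]


class SimConfigError(ValueError):
    """Invalid simulation configuration; message lists the offenders."""


@dataclass(frozen=True)
class SimConfig:
    """Cohort generator parameters.

    Rates are per mapped read: a genome with B background pairs exposes
    2B reads, and its chimeric pair count is Poisson(rate * 2B).  The
    default healthy rate is scaled so the toy genome carries on the order
    of a hundred healthy chimeric pairs per sample — the same order as a
    deep-coverage human genome — and the default tumor/healthy ratio is
    4.42, the cohort-level excess this pipeline is designed to measure.
    """

    seed: int = 0
    n_participants: int = 20
    contigs: dict = field(default_factory=lambda: dict(DEFAULT_CONTIGS))
    sex_chromosomes: frozenset = frozenset({"chrX"})
    mito_name: str = "chrM"
    read_length: int = 100
    mate_gap_mean: float = 150.0
    mate_gap_sd: float = 30.0
    background_pairs: int = 100_000
    mito_background_pairs: int = 2_000
    healthy_chimera_rate: float = 5e-4
    tumor_ratio: float = 4.42
    sex_tumor_ratio: dict | None = None  # e.g. {"female": 4.5, "male": 3.0}
    mito_mixture: tuple = (("ND1", 0.5), ("COX1", 0.3))
    tumor_only_hotspots: tuple = ()
    tumor_only_weight: float = 0.0
    gc_bias_tumor: float = 0.0
    gc_bias_healthy: float = 0.0
    gc_window: int = 25_000
    gc_range: tuple = (0.3, 0.6)
    duplicate_rate: float = 0.0
    plate_size: int = 8
    female_fraction: float = 34 / 57
    coad_fraction: float = 36 / 57
    deceased_fraction: float = 4 / 57

    def validate(self) -> None:
        problems = []
        if self.n_participants < 1:
            problems.append("n_participants must be >= 1")
        if self.healthy_chimera_rate < 0:
            problems.append("healthy_chimera_rate must be >= 0")
        if self.tumor_ratio <= 0:
            problems.append("tumor_ratio must be > 0")
        if not 0 <= self.duplicate_rate < 1:
            problems.append("duplicate_rate must be in [0, 1)")
        if sum(w for _, w in self.mito_mixture) > 1 + 1e-9:
            problems.append("mixture weights must sum to <= 1")
        if not 0 <= self.tumor_only_weight <= 1:
            problems.append("tumor_only_weight must be in [0, 1]")
        if self.mito_name not in self.contigs:
            problems.append(f"mito contig {self.mito_name!r} missing from contigs")
        if self.gc_window <= 0:
            problems.append("gc_window must be > 0")
        if problems:
            raise SimConfigError("; ".join(problems))

    @property
    def build(self) -> GenomeBuild:
        return GenomeBuild(
            dict(self.contigs), frozenset(self.sex_chromosomes), self.mito_name
        )


def _sample_rng(seed: int, sample_id: str, stream: str = "") -> np.random.Generator:
    key = zlib.crc32(f"{sample_id}/{stream}".encode())
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))


# ---------------------------------------------------------------------------
# metadata


def simulate_metadata(config: SimConfig) -> pd.DataFrame:
    """Per-sample metadata table (two rows per participant, t and h).

    Covariate frequencies default to a colorectal tumor/blood cohort mix
    (about 60% female, 63% colon vs rectum, 7% deceased); matched samples
    share every barcode element including the plate.
    """
    rng = _sample_rng(config.seed, "__metadata__")
    rows = []
    for i in range(config.n_participants):
        pid = f"P{i + 1:04d}"
        sex = "female" if rng.random() < config.female_fraction else "male"
        disease = "COAD" if rng.random() < config.coad_fraction else "READ"
        vital = "deceased" if rng.random() < config.deceased_fraction else "alive"
        stage = rng.choice(["I", "II", "III", "IV"], p=[0.2, 0.35, 0.3, 0.15])
        age = int(rng.integers(30, 91))
        race = "white" if rng.random() < 0.8 else "black"
        plate = f"PL{i // config.plate_size + 1:02d}"
        for gt in ("t", "h"):
            rows.append(
                {
                    "sample_id": f"{pid}-{gt}",
                    "participant": pid,
                    "genome_type": gt,
                    "sex": sex,
                    "disease": disease,
                    "vital_status": vital,
                    "stage": stage,
                    "age": age,
                    "race": race,
                    "plate": plate,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth model


def _mixture_arcs(config: SimConfig, tumor: bool):
    """Resolve the hotspot mixture to (weight, arcs) components.

    For tumor genomes, the tumor-only hotspots take ``tumor_only_weight``
    of the breakpoint mass and the shared mixture (plus its uniform
    remainder) is rescaled to the complement, so the shared composition is
    preserved while healthy genomes never draw from tumor-only regions.
    """
    mgn, _, _ = default_mito_annotation(
        config.contigs[config.mito_name], config.mito_name
    )
    arcs_by_id: dict[str, list[Interval]] = {}
    for iv in mgn:
        arcs_by_id.setdefault(iv.id, []).append(iv)
    comps = [(w, arcs_by_id[g]) for g, w in config.mito_mixture]
    rest = 1.0 - sum(w for w, _ in comps)
    if tumor and config.tumor_only_hotspots:
        scale = 1.0 - config.tumor_only_weight
        comps = [(w * scale, arcs) for w, arcs in comps]
        rest *= scale
        per = config.tumor_only_weight / len(config.tumor_only_hotspots)
        comps += [(per, arcs_by_id[g]) for g in config.tumor_only_hotspots]
    return comps, rest


def _draw_mito_positions(
    rng: np.random.Generator, n: int, comps, rest: float, mito_length: int
) -> np.ndarray:
    weights = np.array([w for w, _ in comps] + [rest])
    choice = rng.choice(len(weights), size=n, p=weights / weights.sum())
    out = np.empty(n, dtype=np.int64)
    for k, (_, arcs) in enumerate(comps):
        mask = choice == k
        m = int(mask.sum())
        if m == 0:
            continue
        lens = np.array([a.length for a in arcs], dtype=float)
        arc_idx = rng.choice(len(arcs), size=m, p=lens / lens.sum())
        pos = np.empty(m, dtype=np.int64)
        for j, a in enumerate(arcs):
            sub = arc_idx == j
            pos[sub] = rng.integers(a.start, a.end, size=int(sub.sum()))
        out[mask] = pos
    mask = choice == len(comps)
    out[mask] = rng.integers(0, mito_length, size=int(mask.sum()))
    return out


def gc_window_grid(config: SimConfig) -> IntervalPartition:
    """The fine nuclear window grid carrying the per-window GC targets."""
    from .genome_model import build_windows

    return build_windows(config.build, size=config.gc_window)


def gc_targets(config: SimConfig) -> dict[str, float]:
    """Per-window GC targets, drawn once from the root seed (uniform over
    ``gc_range``) so FASTA emission and landing weights always agree."""
    grid = gc_window_grid(config)
    rng = _sample_rng(config.seed, "__gc__")
    lo, hi = config.gc_range
    return {iv.id: float(rng.uniform(lo, hi)) for iv in grid}


def _landing_weights(grid: IntervalPartition, gc: dict[str, float], beta: float):
    lengths = np.array([iv.length for iv in grid], dtype=float)
    g = np.array([gc[iv.id] for iv in grid])
    w = lengths * np.exp(beta * g)
    return w / w.sum()


def _sample_rates(config: SimConfig, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-sample chimera rate (per mapped read) and Poisson exposure."""
    rows = []
    for r in metadata.itertuples(index=False):
        ratio = config.tumor_ratio
        if config.sex_tumor_ratio and r.sex in config.sex_tumor_ratio:
            ratio = config.sex_tumor_ratio[r.sex]
        rate = config.healthy_chimera_rate * (ratio if r.genome_type == "t" else 1.0)
        rows.append(
            {
                "sample_id": r.sample_id,
                "genome_type": r.genome_type,
                "rate": rate,
                "exposure_reads": 2 * config.background_pairs,
            }
        )
    return pd.DataFrame(rows)


def simulate_truth(config: SimConfig, metadata: pd.DataFrame) -> pd.DataFrame:
    """Draw every implanted chimeric pair (duplicate clones flagged).

    The realized pair count per sample is Poisson(rate * 2 * background
    pairs); each pair gets a mito breakpoint from the hotspot mixture and
    a nuclear landing position from the (possibly GC-biased) window
    weights, uniform within the window.
    """
    grid = gc_window_grid(config)
    gc = gc_targets(config)
    windows = list(grid)
    mito_len = config.contigs[config.mito_name]
    rates = _sample_rates(config, metadata).set_index("sample_id")
    rows = []
    for r in metadata.itertuples(index=False):
        rng = _sample_rng(config.seed, r.sample_id, "chimera")
        tumor = r.genome_type == "t"
        lam = rates.loc[r.sample_id, "rate"] * 2 * config.background_pairs
        n = int(rng.poisson(lam))
        comps, rest = _mixture_arcs(config, tumor)
        mito_pos = _draw_mito_positions(rng, n, comps, rest, mito_len)
        beta = config.gc_bias_tumor if tumor else config.gc_bias_healthy
        weights = _landing_weights(grid, gc, beta)
        widx = rng.choice(len(windows), size=n, p=weights)
        for k in range(n):
            win = windows[widx[k]]
            pos = int(rng.integers(win.start, win.end))
            qname = f"chim_{r.sample_id}_{k}"
            rows.append(
                (r.participant, r.sample_id, r.genome_type, qname,
                 win.contig, pos, int(mito_pos[k]), False)
            )
            if config.duplicate_rate and rng.random() < config.duplicate_rate:
                rows.append(
                    (r.participant, r.sample_id, r.genome_type, qname + ".dup",
                     win.contig, pos, int(mito_pos[k]), True)
                )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


# ---------------------------------------------------------------------------
# count-level cohort


@dataclass
class SimCounts:
    """Count-level simulation output (no read records).

    ``background`` maps sample_id to per-grid-window background *pair*
    counts (each pair contributes two mapped reads to that window);
    ``mito_background`` maps sample_id to sorted mito read positions.
    """

    config: SimConfig
    build: GenomeBuild
    metadata: pd.DataFrame
    truth: pd.DataFrame
    rates: pd.DataFrame
    grid: IntervalPartition
    gc: dict
    background: dict
    mito_background: dict

    def counts_for_partition(
        self, partition: IntervalPartition, drop_duplicates: bool = True
    ) -> pd.DataFrame:
        """Pipeline-equivalent (N, M) counts table for one partition level.

        N tallies chimeric pairs by exact coordinate.  M allocates each
        grid window's background reads to the interval containing the
        window midpoint (the grid is fine relative to every analysis
        partition) plus the chimeric mates themselves; at the ``gen``
        level M keeps autosomal reads only.
        """
        from .alignment_io import COUNT_COLUMNS, MITO_LEVELS

        truth = self.truth
        if drop_duplicates:
            truth = truth[~truth["is_duplicate"]]
        mito_level = partition.level in MITO_LEVELS
        rows = []
        grid_windows = list(self.grid)
        mid_ids = None
        if not mito_level and partition.level != "gen":
            mid_ids = [
                partition.assign(iv.contig, np.array([(iv.start + iv.end) // 2]))[0]
                for iv in grid_windows
            ]
        for r in self.metadata.itertuples(index=False):
            pairs = truth[truth["sample_id"] == r.sample_id]
            if mito_level:
                mito_contig = next(iter(partition.contigs), self.config.mito_name)
                n_counts = partition.count(
                    [mito_contig] * len(pairs), pairs["mito_pos"].tolist()
                )
                mito_reads = self.mito_background[r.sample_id]
                m_counts = partition.count(
                    [mito_contig] * len(mito_reads), mito_reads
                )
                chim_m = partition.count(
                    [mito_contig] * len(pairs), pairs["mito_pos"].tolist()
                )
                for iid in partition.ids:
                    rows.append(
                        (r.sample_id, r.genome_type, iid, n_counts.get(iid, 0),
                         m_counts.get(iid, 0) + chim_m.get(iid, 0))
                    )
            elif partition.level == "gen":
                n_gen = int(
                    pairs["nuclear_contig"].isin(self.build.nuclear_contigs).sum()
                )
                bg = self.background[r.sample_id]
                auto = set(self.build.autosomes)
                m_gen = 2 * int(
                    sum(
                        bg[k]
                        for k, iv in enumerate(grid_windows)
                        if iv.contig in auto
                    )
                )
                m_gen += int(pairs["nuclear_contig"].isin(auto).sum())
                rows.append((r.sample_id, r.genome_type, "gen", n_gen, m_gen))
            else:
                n_counts = partition.count(
                    pairs["nuclear_contig"].tolist(), pairs["nuclear_pos"].tolist()
                )
                bg = self.background[r.sample_id]
                m_counts = {iid: 0 for iid in partition.ids}
                for k, iid in enumerate(mid_ids):
                    if iid is not None:
                        m_counts[iid] += 2 * int(bg[k])
                chim_m = partition.count(
                    pairs["nuclear_contig"].tolist(), pairs["nuclear_pos"].tolist()
                )
                for iid in partition.ids:
                    rows.append(
                        (r.sample_id, r.genome_type, iid, n_counts.get(iid, 0),
                         m_counts.get(iid, 0) + chim_m.get(iid, 0))
                    )
        return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def simulate_counts(config: SimConfig) -> SimCounts:
    """Count-level cohort: chimeric pair truth plus background allocation."""
    config.validate()
    metadata = simulate_metadata(config)
    truth = simulate_truth(config, metadata)
    rates = _sample_rates(config, metadata)
    grid = gc_window_grid(config)
    gc = gc_targets(config)
    lengths = np.array([iv.length for iv in grid], dtype=float)
    probs = lengths / lengths.sum()
    background = {}
    mito_background = {}
    mito_len = config.contigs[config.mito_name]
    for r in metadata.itertuples(index=False):
        rng = _sample_rng(config.seed, r.sample_id, "background")
        background[r.sample_id] = rng.multinomial(config.background_pairs, probs)
        n_mito_reads = 2 * config.mito_background_pairs
        mito_background[r.sample_id] = np.sort(
            rng.integers(0, mito_len, size=n_mito_reads)
        )
    return SimCounts(
        config, config.build, metadata, truth, rates, grid, gc, background,
        mito_background,
    )


# ---------------------------------------------------------------------------
# file-level cohort


def _write_fasta(config: SimConfig, path) -> None:
    """Random sequence hitting the per-window GC targets; chrM at 44% GC."""
    grid = gc_window_grid(config)
    gc = gc_targets(config)
    by_contig: dict[str, list[Interval]] = {}
    for iv in grid:
        by_contig.setdefault(iv.contig, []).append(iv)
    rng = _sample_rng(config.seed, "__fasta__")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    with open(path, "w") as fh:
        for contig, length in config.contigs.items():
            fh.write(f">{contig}\n")
            if contig == config.mito_name:
                chunks = [(length, 0.44)]
            else:
                chunks = [(iv.length, gc[iv.id]) for iv in by_contig[contig]]
            for chunk_len, g in chunks:
                p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
                seq = bases[rng.choice(4, size=chunk_len, p=p)]
                fh.write(seq.tobytes().decode())
                fh.write("\n")


def _write_cytobands(config: SimConfig, path) -> None:
    """Toy cytoband table: each nuclear chromosome split into p/q bands
    with stains cycling over the full UCSC vocabulary."""
    stains = ["gneg", "gpos25", "gpos50", "gpos75", "gpos100", "acen", "gvar",
              "stalk"]
    rng = _sample_rng(config.seed, "__cytobands__")
    with open(path, "w") as fh:
        for contig in config.build.nuclear_contigs:
            length = config.contigs[contig]
            centromere = length // 2
            for arm, (lo, hi) in (("p", (0, centromere)), ("q", (centromere, length))):
                n_bands = 4
                edges = np.linspace(lo, hi, n_bands + 1, dtype=int)
                for b in range(n_bands):
                    stain = stains[int(rng.integers(0, len(stains)))]
                    fh.write(
                        f"{contig}\t{edges[b]}\t{edges[b + 1]}\t"
                        f"{arm}1{b + 1}\t{stain}\n"
                    )


def _sam_header_lines(config: SimConfig) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for contig, length in config.contigs.items():
        lines.append(f"@SQ\tSN:{contig}\tLN:{length}")
    return lines


def _emit_pair(
    lines: list[str], qname: str, c1: str, p1: int, c2: str, p2: int,
    mapq: int, read_length: int, proper: bool, duplicate: bool,
) -> None:
    """Append the two SAM records of a pair (1-based positions on output)."""
    base = 0x1 | (0x2 if proper else 0) | (0x400 if duplicate else 0)
    f1 = base | 0x20 | 0x40  # first of pair, mate reverse
    f2 = base | 0x10 | 0x80  # second of pair, reverse
    tlen = (p2 + read_length) - p1 if c1 == c2 else 0
    cig = f"{read_length}M"
    lines.append(
        f"{qname}\t{f1}\t{c1}\t{p1 + 1}\t{mapq}\t{cig}\t"
        f"{'=' if c2 == c1 else c2}\t{p2 + 1}\t{tlen}\t*\t*"
    )
    lines.append(
        f"{qname}\t{f2}\t{c2}\t{p2 + 1}\t{mapq}\t{cig}\t"
        f"{'=' if c2 == c1 else c1}\t{p1 + 1}\t{-tlen}\t*\t*"
    )


def write_sample_sam(
    config: SimConfig,
    sample_id: str,
    genome_type: str,
    truth_pairs: pd.DataFrame,
    path,
    n_background: int | None = None,
) -> None:
    """One sample's SAM: background concordant pairs, mito-genome pairs and
    the sample's implanted chimeric pairs (clones carry the duplicate flag).
    """
    rng = _sample_rng(config.seed, sample_id, "reads")
    L = config.read_length
    lines = _sam_header_lines(config)
    build = config.build
    nuclear = list(build.nuclear_contigs)
    lengths = np.array([config.contigs[c] for c in nuclear], dtype=float)
    probs = lengths / lengths.sum()
    nbg = config.background_pairs if n_background is None else n_background
    cidx = rng.choice(len(nuclear), size=nbg, p=probs)
    gaps = np.maximum(
        rng.normal(config.mate_gap_mean, config.mate_gap_sd, size=nbg), 0
    ).astype(int)
    for k in range(nbg):
        contig = nuclear[cidx[k]]
        clen = config.contigs[contig]
        span = 2 * L + int(gaps[k])
        p1 = int(rng.integers(0, max(1, clen - span)))
        p2 = p1 + L + int(gaps[k])
        dup = config.duplicate_rate > 0 and rng.random() < config.duplicate_rate
        _emit_pair(lines, f"bg_{sample_id}_{k}", contig, p1, contig, p2,
                   60, L, True, False)
        if dup:
            _emit_pair(lines, f"bg_{sample_id}_{k}.dup", contig, p1, contig, p2,
                       60, L, True, True)
    mito_len = config.contigs[config.mito_name]
    for k in range(config.mito_background_pairs):
        p1 = int(rng.integers(0, max(1, mito_len - 2 * L - 150)))
        _emit_pair(lines, f"mt_{sample_id}_{k}", config.mito_name, p1,
                   config.mito_name, p1 + L + 150, 60, L, True, False)
    for r in truth_pairs.itertuples(index=False):
        npos = min(int(r.nuclear_pos), config.contigs[r.nuclear_contig] - L)
        mpos = min(int(r.mito_pos), mito_len - L)
        _emit_pair(lines, r.query_name, r.nuclear_contig, npos,
                   config.mito_name, mpos, 60, L, False, bool(r.is_duplicate))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_cohort(config: SimConfig, outdir) -> dict:
    """Emit a complete synthetic workspace; returns the path manifest.

    Layout: ``alignments/<sample>.sam``, ``reference.fa`` (+ .fai),
    ``cytobands.tsv``, ``mito_genes.bed``, ``metadata.tsv``, ``truth.tsv``.
    Byte-identical on rerun with the same config.
    """
    import importlib.resources
    import os

    from pyfaidx import Fasta

    config.validate()
    outdir = str(outdir)
    aln_dir = os.path.join(outdir, "alignments")
    os.makedirs(aln_dir, exist_ok=True)
    metadata = simulate_metadata(config)
    truth = simulate_truth(config, metadata)
    fasta_path = os.path.join(outdir, "reference.fa")
    _write_fasta(config, fasta_path)
    Fasta(fasta_path).close()  # builds the .fai
    cyto_path = os.path.join(outdir, "cytobands.tsv")
    _write_cytobands(config, cyto_path)
    bed_path = os.path.join(outdir, "mito_genes.bed")
    ref = importlib.resources.files("numtquant.data") / "mito_genes.bed"
    with importlib.resources.as_file(ref) as p, open(p) as src, open(
        bed_path, "w"
    ) as dst:
        dst.write(src.read())
    meta_path = os.path.join(outdir, "metadata.tsv")
    metadata.to_csv(meta_path, sep="\t", index=False)
    truth_path = os.path.join(outdir, "truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)
    sam_paths = {}
    for r in metadata.itertuples(index=False):
        sam_path = os.path.join(aln_dir, f"{r.sample_id}.sam")
        write_sample_sam(
            config, r.sample_id, r.genome_type,
            truth[truth["sample_id"] == r.sample_id], sam_path,
        )
        sam_paths[r.sample_id] = sam_path
    return {
        "alignments": sam_paths,
        "fasta": fasta_path,
        "cytobands": cyto_path,
        "mito_bed": bed_path,
        "metadata": meta_path,
        "truth": truth_path,
    }


# ---------------------------------------------------------------------------
# truth comparison


def truth_compare(
    detected: pd.DataFrame, truth: pd.DataFrame, drop_duplicates: bool = True
) -> dict:
    """Recovery report for a pipeline run against the generating truth.

    Sensitivity counts detected pairs whose (sample, nuclear contig/pos,
    mito pos) matches an implanted non-duplicate pair; anything detected
    outside the truth table is a false detection.  Per-sample estimated
    tumor/healthy ratio is included when both genome types are present.
    """
    if set(detected["sample_id"]) - set(truth["sample_id"]):
        raise ValueError("detected sample set is not a subset of truth samples")
    t = truth[~truth["is_duplicate"]] if drop_duplicates else truth
    key = ["sample_id", "nuclear_contig", "nuclear_pos", "mito_pos"]
    truth_keys = t.groupby(key).size()
    det_keys = detected.groupby(key).size()
    joined = truth_keys.to_frame("n_truth").join(
        det_keys.to_frame("n_det"), how="outer"
    ).fillna(0)
    found = int(np.minimum(joined["n_truth"], joined["n_det"]).sum())
    n_truth = int(truth_keys.sum())
    false_det = int((joined["n_det"] - joined["n_truth"]).clip(lower=0).sum())
    per_chr_truth = t.groupby("nuclear_contig").size().to_dict()
    per_chr_det = detected.groupby("nuclear_contig").size().to_dict()
    rho = {}
    det_per_sample = detected.groupby("sample_id").size()
    participants = truth[["participant", "sample_id", "genome_type"]].drop_duplicates()
    for pid, grp in participants.groupby("participant"):
        ids = grp.set_index("genome_type")["sample_id"]
        if "t" in ids.index and "h" in ids.index:
            nt = det_per_sample.get(ids["t"], 0)
            nh = det_per_sample.get(ids["h"], 0)
            if nh > 0:
                rho[pid] = nt / nh
    return {
        "sensitivity": found / n_truth if n_truth else 1.0,
        "false_detections": false_det,
        "n_truth_pairs": n_truth,
        "n_detected_pairs": int(len(detected)),
        "per_chromosome_truth": per_chr_truth,
        "per_chromosome_detected": per_chr_det,
        "estimated_ratio_per_participant": rho,
    }
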