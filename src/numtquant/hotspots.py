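"""Mitochondrial fragile sites and nuclear landing-site concentrations.

The mtDNA-side breakpoints of chimeric pairs, binned per mitochondrial
gene (or fixed-size bins), reveal donor hotspots — regions of the
mitochondrial genome over-represented among nuclear transfers.  The
nuclear-side insertion proxies, binned per sliding window, profile the
landing sites.  Regions with tumor support and zero healthy support
across the cohort are flagged as tumor-unique numtogenesis regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .alignment_io import NumtPair, pairs_to_frame
from .genome_model import UNANNOTATED, Interval, IntervalPartition


@dataclass(frozen=True)
class TumorUniqueRegion:
    interval_id: str
    tumor_count: int
    healthy_count: int  # always 0
    n_samples: int


HIST_COLUMNS = ["interval_id", "tumor_count", "healthy_count"]


def _pairs_frame(pairs) -> pd.DataFrame:
    return pairs if isinstance(pairs, pd.DataFrame) else pairs_to_frame(pairs)


def _histogram(
    df: pd.DataFrame,
    partition: IntervalPartition,
    contig_col: str,
    pos_col: str,
    catch_all: bool,
) -> pd.DataFrame:
    ids = list(partition.ids)
    counts = {iid: [0, 0] for iid in ids}
    if catch_all:
        counts[UNANNOTATED] = [0, 0]
    for gtype, col in (("t", 0), ("h", 1)):
        sub = df[df["genome_type"] == gtype]
        if sub.empty:
            continue
        assigned = partition.count(sub[contig_col].tolist(), sub[pos_col].tolist())
        total_assigned = 0
        for iid, c in assigned.items():
            counts[iid][col] += c
            total_assigned += c
        if catch_all:
            counts[UNANNOTATED][col] += len(sub) - total_assigned
    rows = [(iid, t, h) for iid, (t, h) in counts.items()]
    return pd.DataFrame(rows, columns=HIST_COLUMNS)


def mito_breakpoint_histogram(
    pairs: Sequence[NumtPair] | pd.DataFrame,
    mito_partition: IntervalPartition,
) -> pd.DataFrame:
    """Tumor/healthy breakpoint counts per mitochondrial interval.

    Breakpoints falling outside every annotated interval land in the
    catch-all ``unannotated`` bin, so counts always conserve the input
    pair total.
    """
    df = _pairs_frame(pairs)
    mito_contig = next(iter(mito_partition.contigs), "chrM")
    df = df.assign(_mito_contig=mito_contig)
    return _histogram(df, mito_partition, "_mito_contig", "mito_pos", catch_all=True)


def fixed_bin_partition(
    mito_length: int, bin_size: int = 500, mito_name: str = "chrM"
) -> IntervalPartition:
    """Fixed-size mito bins as an annotation-free alternative to genes."""
    ivs = []
    start = 0
    while start < mito_length:
        end = min(start + bin_size, mito_length)
        ivs.append(Interval(f"{mito_name}:{start}-{end}", mito_name, start, end))
        start = end
    return IntervalPartition("mgn", ivs)


def rank_hotspots(
    hist: pd.DataFrame, min_count: int = 1, source: str = "total"
) -> list[str]:
    """Interval ids with count >= min_count, sorted by count descending.

    ``source`` selects the counted column: 'tumor', 'healthy' or 'total'.
    Ties break by genomic order (the histogram's row order); the
    unannotated bin never ranks.
    """
    col = {"tumor": "tumor_count", "healthy": "healthy_count"}.get(source)
    df = hist[hist["interval_id"] != UNANNOTATED].reset_index(drop=True)
    counts = (
        df[col] if col is not None else df["tumor_count"] + df["healthy_count"]
    )
    df = df.assign(_count=counts, _order=range(len(df)))
    df = df[df["_count"] >= min_count]
    df = df.sort_values(["_count", "_order"], ascending=[False, True])
    return df["interval_id"].tolist()


def tumor_unique_regions(
    hist: pd.DataFrame,
    k_min: int = 2,
    pairs: pd.DataFrame | None = None,
    partition: IntervalPartition | None = None,
) -> list[TumorUniqueRegion]:
    """Intervals with zero healthy breakpoints but >= k_min tumor ones.

    When the pair table and partition are supplied, the number of distinct
    supporting tumor samples is reported; otherwise it defaults to the
    tumor pair count (an upper bound).
    """
    out = []
    support: dict[str, int] = {}
    if pairs is not None and partition is not None:
        tums = pairs[pairs["genome_type"] == "t"]
        mito_contig = next(iter(partition.contigs), "chrM")
        for sample_id, grp in tums.groupby("sample_id"):
            assigned = partition.count(
                [mito_contig] * len(grp), grp["mito_pos"].tolist()
            )
            for iid, c in assigned.items():
                if c > 0:
                    support[iid] = support.get(iid, 0) + 1
    for row in hist.itertuples(index=False):
        if row.interval_id == UNANNOTATED:
            continue
        if row.healthy_count == 0 and row.tumor_count >= k_min:
            out.append(
                TumorUniqueRegion(
                    row.interval_id,
                    int(row.tumor_count),
                    0,
                    int(support.get(row.interval_id, row.tumor_count)),
                )
            )
    return out


def nuclear_landing_profile(
    pairs: Sequence[NumtPair] | pd.DataFrame,
    win_partition: IntervalPartition,
) -> pd.DataFrame:
    """Window histogram of nuclear insertion proxies by genome type.

    Suitable as input to the window-level GC association (pairs on contigs
    absent from the window grid are dropped, not binned)."""
    df = _pairs_frame(pairs)
    return _histogram(
        df, win_partition, "nuclear_contig", "nuclear_pos", catch_all=False
    )


def write_histogram_tsv(hist: pd.DataFrame, path) -> None:
    hist.to_csv(path, sep="\t", index=False)


def write_regions_bed(
    regions: Sequence[TumorUniqueRegion], partition: IntervalPartition, path
) -> None:
    by_id: dict[str, list[Interval]] = {}
    for iv in partition:
        by_id.setdefault(iv.id, []).append(iv)
    with open(path, "w") as fh:
        for reg in regions:
            for iv in by_id.get(reg.interval_id, []):
                fh.write(
                    f"{iv.contig}\t{iv.start}\t{iv.end}\t{reg.interval_id}\t"
                    f"{reg.tumor_count}\t.\n"
                )
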