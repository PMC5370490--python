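import numpy as np
import pandas as pd
import pytest

from numtquant.simulate import SimConfig, simulate_counts, write_cohort

SMALL_CONTIGS = {
    "chr1": 2_000_000,
    "chr2": 1_500_000,
    "chrX": 1_000_000,
    "chrM": 16_569,
}


def small_config(**overrides) -> SimConfig:
    """A fast cohort: ~60 chimeric pairs per healthy genome."""
    defaults = dict(
        seed=0,
        n_participants=4,
        contigs=dict(SMALL_CONTIGS),
        background_pairs=3_000,
        mito_background_pairs=300,
        healthy_chimera_rate=5e-3,
        tumor_ratio=3.0,
        gc_window=100_000,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def workspace(tmp_path_factory):
    """A written synthetic workspace (SAMs, FASTA, annotation, truth)."""
    cfg = small_config(duplicate_rate=0.0)
    outdir = tmp_path_factory.mktemp("workspace")
    paths = write_cohort(cfg, outdir)
    return cfg, paths


@pytest.fixture(scope="session")
def count_sim():
    """A count-level cohort shared across tests."""
    return simulate_counts(small_config())


def write_sam(path, records, contigs=SMALL_CONTIGS):
    """Write a SAM from (qname, flag, contig, pos0, mapq, mate_contig,
    mate_pos0) tuples; positions 0-based here, 1-based on disk."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in contigs.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    for qname, flag, contig, pos, mapq, mcontig, mpos in records:
        rnext = "=" if mcontig == contig else mcontig
        lines.append(
            f"{qname}\t{flag}\t{contig}\t{pos + 1}\t{mapq}\t100M\t"
            f"{rnext}\t{mpos + 1}\t0\t*\t*"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def pair_records(qname, c1, p1, c2, p2, mapq=60, dup=False, proper=False):
    """Both mates of one pair as write_sam tuples."""
    base = 0x1 | (0x2 if proper else 0) | (0x400 if dup else 0)
    return [
        (qname, base | 0x20 | 0x40, c1, p1, mapq, c2, p2),
        (qname, base | 0x10 | 0x80, c2, p2, mapq, c1, p1),
    ]
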