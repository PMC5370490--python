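import numpy as np
import pandas as pd
import pytest

from numtquant.alignment_io import (
    FDUP,
    FSECONDARY,
    MitoContigError,
    ReadRecord,
    build_sample_counts,
    count_mapped_reads,
    count_mapped_reads_by_contig,
    extract_numt_pairs,
    filter_reads,
    mark_duplicates,
    pairs_to_frame,
    read_alignments,
)
from numtquant.genome_model import (
    GenomeBuild,
    Interval,
    IntervalPartition,
    build_windows,
    make_chromosome_partition,
    make_genome_partition,
)

from conftest import SMALL_CONTIGS, pair_records, write_sam


def rec(qname="q", contig="chr1", pos=100, mate="chr1", mpos=300, mapq=60,
        flag=0x1):
    return ReadRecord(qname, contig, pos, mate, mpos, mapq, flag)


class TestIngestion:
    def test_identity_ingestion(self, tmp_path):
        records = pair_records("a", "chr1", 100, "chr1", 400) + pair_records(
            "b", "chr2", 10, "chrM", 5000
        ) + pair_records("c", "chrX", 0, "chrX", 250)
        path = write_sam(tmp_path / "six.sam", records)
        got = list(read_alignments(path))
        assert len(got) == 6
        assert [r.query_name for r in got] == ["a", "a", "b", "b", "c", "c"]
        # 1-based on disk -> 0-based in memory
        assert got[0].pos == 100 and got[0].mate_pos == 400

    def test_empty_sam(self, tmp_path):
        path = write_sam(tmp_path / "empty.sam", [])
        assert list(read_alignments(path)) == []

    def test_secondary_excluded_mode(self, tmp_path):
        records = []
        for k in range(4):
            records += pair_records(f"q{k}", "chr1", 100 * k, "chr1", 100 * k + 300)
        records += [
            ("q0", 0x1 | FSECONDARY, "chr2", 55, 20, "chr1", 400),
            ("q1", 0x1 | FSECONDARY, "chr2", 66, 20, "chr1", 400),
        ]
        path = write_sam(tmp_path / "sec.sam", records)
        full = list(read_alignments(path))
        assert len(full) == 10
        kept = list(filter_reads(full, drop_secondary_supplementary=True))
        assert len(kept) == 8


class TestFilters:
    def test_duplicate_drop_by_flag_count(self):
        stream = [rec(qname=f"q{i}", flag=0x1 | (FDUP if i < 3 else 0))
                  for i in range(10)]
        assert len(list(filter_reads(stream, drop_duplicates=True))) == 7

    def test_min_mapq_zero_is_identity(self):
        stream = [rec(qname=f"q{i}", mapq=i) for i in range(5)]
        assert list(filter_reads(stream, min_mapq=0)) == stream

    def test_mapq_threshold(self):
        stream = [rec(qname=f"q{i}", mapq=m) for i, m in
                  enumerate([0, 10, 20, 30, 60])]
        kept = list(filter_reads(stream, min_mapq=20))
        assert [r.mapq for r in kept] == [20, 30, 60]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        stream = [
            rec(qname=f"q{i}", mapq=int(rng.integers(0, 61)),
                flag=0x1 | (FDUP if rng.random() < 0.3 else 0)
                | (FSECONDARY if rng.random() < 0.2 else 0))
            for i in range(200)
        ]
        once = list(filter_reads(stream, min_mapq=10))
        twice = list(filter_reads(once, min_mapq=10))
        assert once == twice

    def test_order_preserved(self):
        stream = [rec(qname=f"q{i}") for i in range(20)]
        assert [r.query_name for r in filter_reads(stream)] == [
            f"q{i}" for i in range(20)
        ]

    def test_internal_duplicate_marker(self):
        a = rec(qname="a", pos=5, mpos=9)
        b = rec(qname="b", pos=5, mpos=9)  # same signature
        c = rec(qname="c", pos=6, mpos=9)
        marked = mark_duplicates([a, b, c])
        assert [r.is_duplicate for r in marked] == [False, True, False]


class TestExtraction:
    def test_definitional_pair(self):
        stream = [
            rec(qname="p", contig="chr1", pos=1000, mate="chrM", mpos=5000),
            rec(qname="p", contig="chrM", pos=5000, mate="chr1", mpos=1000,
                mapq=40),
        ]
        pairs = extract_numt_pairs(stream, sample_id="s1", genome_type="t")
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.nuclear_contig, p.nuclear_pos, p.mito_pos) == ("chr1", 1000, 5000)
        assert p.min_mapq == 40  # min over the two mates

    def test_non_chimeric_pairs_excluded(self):
        stream = [
            rec(qname="nn", contig="chr1", mate="chr2"),
            rec(qname="nn", contig="chr2", mate="chr1"),
            rec(qname="mm", contig="chrM", mate="chrM"),
            rec(qname="mm", contig="chrM", mate="chrM"),
        ]
        assert extract_numt_pairs(stream) == []

    def test_orphan_reconstruction(self):
        # only the mito-side record survives filtering; mate fields recover
        # the nuclear proxy
        stream = [rec(qname="o", contig="chrM", pos=7000, mate="chr2",
                      mpos=123_456, mapq=50)]
        pairs = extract_numt_pairs(stream)
        assert len(pairs) == 1
        assert pairs[0].nuclear_contig == "chr2"
        assert pairs[0].nuclear_pos == 123_456
        assert pairs[0].mito_pos == 7000
        assert pairs[0].min_mapq == 50

    def test_unmapped_mate_excluded(self):
        stream = [rec(qname="u", contig="chrM", mate="chr1", flag=0x1 | 0x8)]
        assert extract_numt_pairs(stream) == []

    def test_unknown_mito_name_lists_contigs(self):
        with pytest.raises(MitoContigError, match="chr1"):
            extract_numt_pairs([], mito_names={"chrMT_weird"},
                               contigs=["chr1", "chr2"])

    def test_simulator_output_matches_truth(self, tmp_path):
        """37 implanted chimeras among concordant + nuclear-nuclear pairs."""
        rng = np.random.default_rng(7)
        records = []
        truth = []
        for k in range(37):
            c = ("chr1", "chr2", "chrX")[k % 3]
            npos, mpos = int(rng.integers(0, 10**6)), int(rng.integers(0, 16569))
            records += pair_records(f"chim{k}", c, npos, "chrM", mpos)
            truth.append((c, npos, mpos))
        for k in range(10_000):
            c = ("chr1", "chr2")[k % 2]
            p = int(rng.integers(0, 10**6))
            records += pair_records(f"bg{k}", c, p, c, p + 250, proper=True)
        for k in range(5):
            records += pair_records(f"mm{k}", "chr1", k * 10, "chr2", k * 20)
        path = write_sam(tmp_path / "sim.sam", records)
        pairs = extract_numt_pairs(list(read_alignments(path)), sample_id="s")
        assert len(pairs) == 37
        got = sorted((p.nuclear_contig, p.nuclear_pos, p.mito_pos) for p in pairs)
        assert got == sorted(truth)


def brute_force_pairs(records):
    """Oracle: group by query_name, test the mito/nuclear condition on the
    mates' own contigs."""
    by_name = {}
    for r in records:
        if not r.is_unmapped and r.is_paired:
            by_name.setdefault(r.query_name, []).append(r)
    out = []
    for name, recs in by_name.items():
        if len(recs) != 2:
            # fall back to mate fields exactly like a single-record pair
            r = recs[0]
            if r.mate_is_unmapped:
                continue
            sides = {r.contig: r.pos, r.mate_contig: r.mate_pos}
        else:
            if any(r.mate_is_unmapped for r in recs):
                continue
            sides = {r.contig: r.pos for r in recs}
        mito = [c for c in sides if c == "chrM"]
        nuc = [c for c in sides if c != "chrM"]
        if len(mito) == 1 and len(nuc) == 1 and len(sides) == 2:
            out.append((nuc[0], sides[nuc[0]], sides[mito[0]]))
    return sorted(out)


class TestOracleEquivalence:
    def test_random_sam_matches_bruteforce(self, tmp_path):
        rng = np.random.default_rng(11)
        contigs = list(SMALL_CONTIGS)
        records = []
        for k in range(2_000):
            c1 = contigs[rng.integers(0, len(contigs))]
            c2 = contigs[rng.integers(0, len(contigs))]
            p1 = int(rng.integers(0, SMALL_CONTIGS[c1] - 100))
            p2 = int(rng.integers(0, SMALL_CONTIGS[c2] - 100))
            records += pair_records(f"r{k}", c1, p1, c2, p2,
                                    mapq=int(rng.integers(0, 61)))
        path = write_sam(tmp_path / "rand.sam", records)
        stream = list(read_alignments(path))
        impl = sorted(
            (p.nuclear_contig, p.nuclear_pos, p.mito_pos)
            for p in extract_numt_pairs(stream)
        )
        assert impl == brute_force_pairs(stream)


class TestCounting:
    def test_single_window_count(self):
        part = IntervalPartition(
            "win", [Interval("w1", "chr1", 0, 1000), Interval("w2", "chr1", 1000,
                                                              2000)]
        )
        stream = [rec(qname=f"q{i}", pos=i) for i in range(100)]
        counts = count_mapped_reads(stream, part)
        assert counts == {"w1": 100, "w2": 0}

    def test_empty_stream_zeros(self):
        part = IntervalPartition("win", [Interval("w", "chr1", 0, 10)])
        assert count_mapped_reads([], part) == {"w": 0}

    def test_boundary_straddle_matches_bruteforce(self):
        part = IntervalPartition(
            "win", [Interval("a", "chr1", 0, 500), Interval("b", "chr1", 500,
                                                            1000)]
        )
        rng = np.random.default_rng(3)
        stream = [rec(qname=f"q{i}", pos=int(rng.integers(400, 600)))
                  for i in range(50)]
        counts = count_mapped_reads(stream, part)
        assert counts["a"] == sum(1 for r in stream if r.pos < 500)
        assert counts["b"] == sum(1 for r in stream if r.pos >= 500)

    def test_off_partition_contigs_ignored(self):
        part = IntervalPartition("win", [Interval("w", "chr1", 0, 1000)])
        stream = [rec(qname="a", contig="chrUn_x", pos=5)]
        assert count_mapped_reads(stream, part) == {"w": 0}


class TestSampleCounts:
    def test_zero_pairs_all_zero_n(self):
        part = IntervalPartition("win", [Interval("w", "chr1", 0, 1000)])
        out = build_sample_counts([], {"w": 10}, part, "s", "t")
        assert out["numt_count"].tolist() == [0]
        assert out["mapped_count"].tolist() == [10]

    def test_pairs_in_window(self):
        from numtquant.alignment_io import NumtPair

        part = IntervalPartition("win", [Interval("w", "chr1", 0, 1000)])
        pairs = [NumtPair("s", "t", "chr1", i, 5, 60) for i in range(5)]
        out = build_sample_counts(pairs, {"w": 10**6}, part, "s", "t")
        assert out.iloc[0]["numt_count"] == 5
        assert out.iloc[0]["mapped_count"] == 10**6

    def test_gen_level_excludes_sex_reads_from_m_only(self, count_sim):
        build = count_sim.build
        gen = make_genome_partition(build)
        chr_part = make_chromosome_partition(build)
        counts_gen = count_sim.counts_for_partition(gen)
        counts_chr = count_sim.counts_for_partition(chr_part)
        for sid, grp in counts_chr.groupby("sample_id"):
            gen_row = counts_gen[counts_gen["sample_id"] == sid].iloc[0]
            # N: all nuclear contigs incl. chrX
            assert gen_row["numt_count"] == grp["numt_count"].sum()
            # M: autosomes only
            auto = grp[grp["interval_id"].isin(build.autosomes)]
            assert gen_row["mapped_count"] == auto["mapped_count"].sum()

    def test_simulated_per_chromosome_n_matches_truth(self, count_sim):
        chr_part = make_chromosome_partition(count_sim.build)
        counts = count_sim.counts_for_partition(chr_part)
        truth = count_sim.truth[~count_sim.truth["is_duplicate"]]
        for (sid, contig), grp in truth.groupby(["sample_id", "nuclear_contig"]):
            row = counts[(counts["sample_id"] == sid)
                         & (counts["interval_id"] == contig)]
            assert int(row["numt_count"].iloc[0]) == len(grp)

    def test_window_m_sums_to_chromosome_m(self, count_sim):
        build = count_sim.build
        win = count_sim.grid
        chr_part = make_chromosome_partition(build)
        counts_win = count_sim.counts_for_partition(win)
        counts_chr = count_sim.counts_for_partition(chr_part)
        win_contig = {iv.id: iv.contig for iv in win}
        for sid in count_sim.metadata["sample_id"]:
            cw = counts_win[counts_win["sample_id"] == sid].copy()
            cw["contig"] = cw["interval_id"].map(win_contig)
            per_chr = cw.groupby("contig")["mapped_count"].sum()
            cc = counts_chr[counts_chr["sample_id"] == sid].set_index(
                "interval_id"
            )["mapped_count"]
            for contig in build.nuclear_contigs:
                assert per_chr[contig] == cc[contig]


class TestDuplicateMonotonicity:
    def test_dropping_duplicates_never_increases_counts(self, tmp_path):
        rng = np.random.default_rng(5)
        records = []
        for k in range(300):
            c = ("chr1", "chrM")[int(rng.random() < 0.3)]
            dup = rng.random() < 0.25
            p1 = int(rng.integers(0, 10**5))
            records += pair_records(f"q{k}", c, p1, "chr1", p1 + 300, dup=dup)
        path = write_sam(tmp_path / "dups.sam", records)
        part = build_windows(
            GenomeBuild(SMALL_CONTIGS, frozenset({"chrX"}), "chrM"), 500_000
        )
        stream = list(read_alignments(path))
        kept = list(filter_reads(stream, drop_duplicates=True))
        all_recs = list(filter_reads(stream, drop_duplicates=False))
        m_kept = count_mapped_reads(kept, part)
        m_all = count_mapped_reads(all_recs, part)
        assert all(m_kept[i] <= m_all[i] for i in m_all)
        n_kept = len(extract_numt_pairs(kept))
        n_all = len(extract_numt_pairs(all_recs))
        assert n_kept <= n_all
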