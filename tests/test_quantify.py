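"""Read counting semantics, parallel jobs, cohort aggregation, argmax rules."""

import pandas as pd
import pysam
import pytest

from hervotrace.query import GenomicFragment
from hervotrace.quantify import (
    NO_READ,
    CountingMode,
    FragmentCountMatrix,
    SampleManifest,
    aggregate_cohort,
    count_fragment_reads,
    fragment_label,
    merge_matrices,
    most_expressed_per_sample,
    most_expressed_tissue,
    run_quantification_jobs,
    task_status,
)

CONTIG_LEN = 5000


def _frag(pid="p", chrom="chr1", start=1001, end=1027, strand="+"):
    return GenomicFragment(pid, chrom, start, end, strand, sources=[])


def _make_bam(path, records, contigs=("chr1", "chr2")):
    """records: (chrom, pos0, read_len, nh, secondary) tuples."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": CONTIG_LEN} for c in contigs],
    }
    tid = {c: i for i, c in enumerate(contigs)}
    unsorted = path.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as bam:
        for i, (chrom, pos0, rlen, nh, secondary) in enumerate(records):
            a = pysam.AlignedSegment()
            a.query_name = f"r{i}" if nh == 1 else f"mm{i // 2}"
            a.reference_id = tid[chrom]
            a.reference_start = pos0
            a.mapping_quality = 50
            a.cigartuples = [(0, rlen)]
            a.query_sequence = "A" * rlen
            a.flag = 0x100 if secondary else 0
            a.set_tag("NH", nh)
            bam.write(a)
    pysam.sort("-o", str(path), str(unsorted))
    unsorted.unlink()
    pysam.index(str(path))
    return path


class TestCountFragmentReads:
    def test_unique_reads_inside_fragment(self, tmp_path):
        frag = _frag()
        bam = _make_bam(
            tmp_path / "a.bam", [("chr1", 1000 + i, 20, 1, False) for i in range(5)]
        )
        counts = count_fragment_reads(bam, [frag])
        assert counts[fragment_label(frag)] == 5

    def test_zero_overlap_contributes_nothing(self, tmp_path):
        frag = _frag()
        bam = _make_bam(tmp_path / "a.bam", [("chr1", 2000, 20, 1, False)])
        assert count_fragment_reads(bam, [frag])[fragment_label(frag)] == 0

    def test_multimapped_excluded_by_default_fractional_by_nh(self, tmp_path):
        frag = _frag()
        bam = _make_bam(
            tmp_path / "a.bam",
            [("chr1", 1005, 20, 2, False), ("chr2", 1005, 20, 2, True)],
        )
        assert count_fragment_reads(bam, [frag])[fragment_label(frag)] == 0
        frac = CountingMode(count_multimapped=True, fractional=True)
        assert count_fragment_reads(bam, [frag], frac)[fragment_label(frag)] == 0.5

    def test_read_spanning_two_overlapping_fragments_counts_in_both(self, tmp_path):
        outer = _frag("out", start=1001, end=1045)
        inner = _frag("in", start=1010, end=1036)
        bam = _make_bam(tmp_path / "a.bam", [("chr1", 1009, 30, 1, False)])
        counts = count_fragment_reads(bam, [outer, inner])
        assert counts[fragment_label(outer)] == 1
        assert counts[fragment_label(inner)] == 1

    def test_min_overlap_threshold(self, tmp_path):
        frag = _frag()
        # read overlaps the fragment by exactly 3 bases
        bam = _make_bam(tmp_path / "a.bam", [("chr1", 997, 6, 1, False)])
        assert count_fragment_reads(
            bam, [frag], CountingMode(min_overlap_bp=3)
        )[fragment_label(frag)] == 1
        assert count_fragment_reads(
            bam, [frag], CountingMode(min_overlap_bp=4)
        )[fragment_label(frag)] == 0

    def test_missing_index_is_an_error(self, tmp_path):
        bam = _make_bam(tmp_path / "a.bam", [("chr1", 1000, 20, 1, False)])
        bam.with_suffix(".bam.bai").unlink()
        with pytest.raises(FileNotFoundError):
            count_fragment_reads(bam, [_frag()])

    def test_chromosome_mismatch_names_offenders(self, tmp_path):
        bam = _make_bam(tmp_path / "a.bam", [("chr1", 1000, 20, 1, False)])
        with pytest.raises(ValueError, match="chrZ"):
            count_fragment_reads(bam, [_frag(chrom="chrZ")])

    def test_unique_mode_conservation_disjoint_fragments(self, tmp_path):
        """Sum over disjoint fragments equals distinct overlapping reads."""
        frags = [_frag("a", start=1001, end=1027), _frag("b", start=2001, end=2027)]
        records = [("chr1", 990 + 7 * i, 25, 1, False) for i in range(8)]
        records += [("chr1", 1990 + 9 * i, 25, 1, False) for i in range(4)]
        records += [("chr1", 3000, 25, 1, False)]  # overlaps nothing
        bam = _make_bam(tmp_path / "a.bam", records)
        counts = count_fragment_reads(bam, frags)
        n_overlapping = sum(
            1
            for _, pos0, rlen, _, _ in records
            if any(pos0 < f.end and pos0 + rlen > f.start - 1 for f in frags)
        )
        assert sum(counts.values()) == n_overlapping

    def test_fractional_conservation_across_loci(self, tmp_path):
        """An NH=2 read overlapping one fragment per alignment contributes 1."""
        frags = [_frag("a", chrom="chr1"), _frag("b", chrom="chr2")]
        bam = _make_bam(
            tmp_path / "a.bam",
            [("chr1", 1005, 20, 2, False), ("chr2", 1005, 20, 2, True)],
        )
        frac = CountingMode(count_multimapped=True, fractional=True)
        counts = count_fragment_reads(bam, frags, frac)
        assert sum(counts.values()) == pytest.approx(1.0)


class TestJobsAndMerge:
    def test_worker_invariance_on_cohort(self, cohort, fragments, manifest):
        m1, _ = run_quantification_jobs(manifest, fragments, workers=1)
        m4, _ = run_quantification_jobs(manifest, fragments, workers=4)
        pd.testing.assert_frame_equal(m1.counts, m4.counts)

    def test_truth_recovery_unique_mode(self, cohort, fragments, manifest):
        truth = cohort["truth"]
        matrix, _ = run_quantification_jobs(manifest, fragments, workers=2)
        for sid in matrix.counts.columns:
            for label in matrix.counts.index:
                assert matrix.counts.loc[label, sid] == truth.counts_unique[sid][label]

    def test_task_status_roundtrip_and_unknown_id(self, tmp_path, cohort, fragments, manifest):
        _, task_id = run_quantification_jobs(
            manifest, fragments, workers=2, task_dir=tmp_path
        )
        status = task_status(tmp_path, task_id)
        assert all(s["state"] == "done" for s in status["samples"].values())
        with pytest.raises(KeyError):
            task_status(tmp_path, "nope")

    def test_failed_sample_withheld_not_fatal(self, tmp_path, fragments, manifest):
        rows = manifest.rows[:2] + [("broken", "px", "tumor", str(tmp_path / "no.bam"))]
        mf = SampleManifest(rows)
        matrix, tid = run_quantification_jobs(mf, fragments, workers=2, task_dir=tmp_path)
        assert "broken" not in matrix.counts.columns
        assert task_status(tmp_path, tid)["samples"]["broken"]["state"] == "failed"

    def test_merge_partials_and_duplicate_guard(self, cohort, fragments, manifest):
        mf_a = SampleManifest(manifest.rows[:2])
        mf_b = SampleManifest(manifest.rows[2:4])
        full, _ = run_quantification_jobs(
            SampleManifest(manifest.rows[:4]), fragments
        )
        part_a, _ = run_quantification_jobs(mf_a, fragments)
        part_b, _ = run_quantification_jobs(mf_b, fragments)
        merged = merge_matrices([part_a, part_b])
        pd.testing.assert_frame_equal(
            merged.counts, full.counts[sorted(full.counts.columns)]
        )
        with pytest.raises(ValueError, match="duplicate"):
            merge_matrices([part_a, part_a])


class TestAggregation:
    def _matrix(self, data, samples):
        df = pd.DataFrame(data, dtype=float)
        df.columns = samples
        return FragmentCountMatrix(counts=df, mode=CountingMode())

    def _manifest(self, samples, groups):
        return SampleManifest(
            [(s, f"pt{i}", g, "x.bam") for i, (s, g) in enumerate(zip(samples, groups))]
        )

    def test_group_sums(self):
        m = self._matrix(
            {"T1": {"p|chr1:1-27|+": 2}, "T2": {"p|chr1:1-27|+": 3}, "N1": {"p|chr1:1-27|+": 4}},
            ["T1", "T2", "N1"],
        )
        mf = self._manifest(["T1", "T2", "N1"], ["tumor", "tumor", "normal"])
        agg = aggregate_cohort(m, mf)
        row = agg.loc["p|chr1:1-27|+"]
        assert (row.tumor_reads, row.normal_reads, row.total_reads) == (5, 4, 9)

    def test_sample_missing_from_manifest_is_an_error(self):
        m = self._matrix({"T1": {"p|chr1:1-27|+": 2}}, ["T1"])
        with pytest.raises(KeyError):
            aggregate_cohort(m, self._manifest(["X"], ["tumor"]))

    def test_most_expressed_tie_breaks_by_coordinate(self):
        idx = ["p|chr1:500-526|+", "p|chr1:100-126|+"]
        df = pd.DataFrame(
            {"tumor_reads": [5.0, 5.0], "normal_reads": [0.0, 0.0], "total_reads": [5.0, 5.0]},
            index=idx,
        )
        [rec] = most_expressed_tissue(df)
        assert rec.fragment == "chr1:100-126"

    def test_most_expressed_all_zero_is_no_read(self):
        df = pd.DataFrame(
            {"tumor_reads": [0.0], "normal_reads": [0.0], "total_reads": [0.0]},
            index=["p|chr1:100-126|+"],
        )
        [rec] = most_expressed_tissue(df)
        assert rec.fragment == NO_READ

    def test_rank_by_tumor_flag(self):
        idx = ["p|chr1:100-126|+", "p|chr1:500-526|+"]
        df = pd.DataFrame(
            {"tumor_reads": [1.0, 9.0], "normal_reads": [20.0, 0.0],
             "total_reads": [21.0, 9.0]},
            index=idx,
        )
        assert most_expressed_tissue(df)[0].fragment == "chr1:100-126"
        assert most_expressed_tissue(df, rank_by="tumor")[0].fragment == "chr1:500-526"

    def test_per_sample_argmax_and_no_read(self):
        idx = ["p|chr1:100-126|+", "p|chr1:500-526|+"]
        df = pd.DataFrame({"S1": [0.0, 3.0], "S2": [0.0, 0.0]}, index=idx)
        m = FragmentCountMatrix(counts=df, mode=CountingMode())
        table = most_expressed_per_sample(m)
        assert table.loc["p", "S1"] == "chr1:500-526"
        assert table.loc["p", "S2"] == NO_READ

    def test_tumor_le_total_on_cohort(self, cohort, fragments, manifest):
        matrix, _ = run_quantification_jobs(manifest, fragments, workers=2)
        agg = aggregate_cohort(matrix, manifest)
        for rec in most_expressed_tissue(agg):
            assert rec.tumor_reads <= rec.total_reads
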