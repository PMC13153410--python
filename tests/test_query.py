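"""Peptide search, fragment derivation, and GTF emission."""

import numpy as np
import pytest

from hervotrace._seq import revcomp, translate
from hervotrace.query import (
    GenomicFragment,
    PeptideHit,
    PeptideQuery,
    QueryConfig,
    find_peptide_hits,
    hit_to_fragments,
    load_peptides,
    merge_fragments,
    read_gtf,
    write_gtf,
)
from hervotrace.reference_db import (
    CoordinatePlacement,
    HervRegion,
    OpenReadingFrame,
    OrfDatabase,
    build_database,
)

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _db_from_proteins(proteins, chrom="chr9", start=1000):
    """A database of hand-placed ORFs (placements are consistent spans but the
    underlying sequence is irrelevant for substring search tests)."""
    orfs = []
    regions = {}
    pos = start
    for i, prot in enumerate(proteins):
        rid = f"R{i}"
        span = 3 * len(prot)
        seq = "A" * span
        regions[rid] = HervRegion(rid, chrom, pos, pos + span - 1, "+", seq)
        orfs.append(
            OpenReadingFrame(
                orf_id=f"O{i}", region_id=rid, frame="+1", protein=prot,
                placements=[CoordinatePlacement(chrom, pos, pos + span - 1, "+")],
            )
        )
        pos += span + 100
    return OrfDatabase(regions=regions, orfs=orfs)


class TestFindPeptideHits:
    def test_single_occurrence(self):
        db = _db_from_proteins(["MMMAVLLPQPPKMMM"])
        hits = find_peptide_hits(PeptideQuery("p", "AVLLPQPPK"), db)
        assert len(hits) == 1 and hits[0].protein_offset == 3

    def test_one_residue_difference_is_no_hit(self):
        db = _db_from_proteins(["MMMAVLLPQPPKMMM"])
        assert find_peptide_hits(PeptideQuery("p", "AVLLPQPPA"), db) == []

    def test_two_offsets_two_hits(self):
        db = _db_from_proteins(["MKLMKLMKL"])
        hits = find_peptide_hits(PeptideQuery("p", "MKLMKL"), db)
        assert [h.protein_offset for h in hits] == [0, 3]

    def test_empty_database_rejected(self):
        db = OrfDatabase(regions={}, orfs=[])
        with pytest.raises(ValueError):
            find_peptide_hits(PeptideQuery("p", "AVLLPQPPK"), db)

    def test_random_database_matches_bruteforce_scan(self):
        rng = np.random.default_rng(42)
        proteins = ["".join(AA[rng.integers(0, 20, 40)]) for _ in range(200)]
        db = _db_from_proteins(proteins)
        queries = []
        for _ in range(25):  # guaranteed-present substrings
            p = proteins[rng.integers(0, 200)]
            s = rng.integers(0, len(p) - 9)
            queries.append(p[s : s + 9])
        for _ in range(25):  # mostly-absent random 9-mers
            queries.append("".join(AA[rng.integers(0, 20, 9)]))
        for q in queries:
            got = {
                (h.orf_id, h.protein_offset)
                for h in find_peptide_hits(PeptideQuery("q", q), db)
            }
            expected = {
                (f"O{i}", j)
                for i, prot in enumerate(proteins)
                for j in range(len(prot) - len(q) + 1)
                if prot[j : j + len(q)] == q
            }
            assert got == expected

    def test_monotonicity_adding_orfs_never_removes_hits(self):
        base = ["MMMAVLLPQPPKMMM", "KKKK"]
        pep = PeptideQuery("p", "AVLLPQPPK")
        small = _db_from_proteins(base)
        big = _db_from_proteins(base + ["AVLLPQPPKAVLLPQPPK"])
        assert len(find_peptide_hits(pep, big)) >= len(find_peptide_hits(pep, small))


class TestBlastpBackend:
    def test_blastp_subset_of_exact(self):
        proteins = ["MMMAVLLPQPPKMMMM" * 2, "GILLPQPPKAAAAAAA", "KLMNPQRSTVWYACDE"]
        db = _db_from_proteins(proteins)
        pep = PeptideQuery("p", "AVLLPQPPK")
        exact = {
            (h.orf_id, h.protein_offset) for h in find_peptide_hits(pep, db)
        }
        blast = {
            (h.orf_id, h.protein_offset)
            for h in find_peptide_hits(pep, db, QueryConfig(backend="blastp"))
        }
        assert blast <= exact and len(blast) >= 1


class TestHitToFragments:
    def _db_with_placement(self, protein, chrom, start, end, strand):
        region_seq = "A" * (end - start + 1)
        region = HervRegion("R", chrom, start, end, "+", region_seq)
        orf = OpenReadingFrame(
            orf_id="O", region_id="R", frame="+1", protein=protein,
            placements=[CoordinatePlacement(chrom, start, end, strand)],
            provenance="synthetic",  # skip reference round-trip (dummy sequence)
        )
        return OrfDatabase(regions={"R": region}, orfs=[orf])

    def test_published_minus_strand_nine_mer_interval(self):
        """A 9-mer at offset 0 of an ORF placed at chr11:70055837-70055863 '-'
        maps to exactly that interval, span 27."""
        db = self._db_with_placement("VILPPQPPK", "chr11", 70055837, 70055863, "-")
        hit = PeptideHit("P1", "O", 0, 100.0, 9)
        [frag] = hit_to_fragments(hit, db)
        assert (frag.start, frag.end, frag.strand) == (70055837, 70055863, "-")

    def test_published_fifteen_mer_span_45(self):
        db = self._db_with_placement(
            "NEAIEQVRAICLRAW", "chr1", 155603245, 155603289, "-"
        )
        [frag] = hit_to_fragments(PeptideHit("PO4", "O", 0, 100.0, 15), db)
        assert (frag.start, frag.end) == (155603245, 155603289)
        assert frag.end - frag.start + 1 == 45

    def test_plus_placement_offset_zero_is_whole_interval(self):
        db = self._db_with_placement("QQQQQQQQQQ", "chr2", 100, 129, "+")
        [frag] = hit_to_fragments(PeptideHit("p", "O", 0, 100.0, 10), db)
        assert (frag.start, frag.end, frag.strand) == (100, 129, "+")

    def test_offset_arithmetic_on_both_strands(self):
        db = self._db_with_placement("ABCDEFGHIK".replace("B", "W"), "chr2", 100, 129, "+")
        [plus] = hit_to_fragments(PeptideHit("p", "O", 2, 100.0, 3), db)
        assert (plus.start, plus.end) == (106, 114)
        db2 = self._db_with_placement("AWCDEFGHIK", "chr2", 100, 129, "-")
        [minus] = hit_to_fragments(PeptideHit("p", "O", 2, 100.0, 3), db2)
        assert (minus.start, minus.end) == (115, 123)

    def test_fragment_round_trip_on_real_database(self, reference_db, cohort):
        """Fragments from the planted cohort translate back to their peptides."""
        truth = cohort["truth"]
        genome = cohort["genome"]
        for pid, pep_seq in truth.peptides.items():
            for hit in find_peptide_hits(PeptideQuery(pid, pep_seq), reference_db):
                for frag in hit_to_fragments(hit, reference_db):
                    sub = genome[frag.chrom][frag.start - 1 : frag.end]
                    if frag.strand == "-":
                        sub = revcomp(sub)
                    assert translate(sub) == pep_seq
                    assert frag.end - frag.start + 1 == 3 * len(pep_seq)


class TestMergeAndGtf:
    def _frag(self, pid="p", chrom="chr1", start=100, end=126, strand="+"):
        return GenomicFragment(pid, chrom, start, end, strand, sources=[])

    def test_identical_windows_merge(self):
        out = merge_fragments([self._frag(), self._frag()])
        assert len(out) == 1

    def test_distinct_windows_kept_sorted(self):
        out = merge_fragments([self._frag(start=400, end=426), self._frag()])
        assert [f.start for f in out] == [100, 400]
        assert merge_fragments([]) == []

    def test_gtf_round_trip(self, tmp_path, fragments):
        path = tmp_path / "frags.gtf"
        write_gtf(fragments, path)
        lines = [l for l in path.read_text().splitlines() if l]
        assert len(lines) == len(fragments)
        for line in lines:
            cols = line.split("\t")
            assert len(cols) == 9
            assert int(cols[3]) <= int(cols[4])
            assert cols[2] == "HERV_fragment"
        back = read_gtf(path)
        assert [
            (f.peptide_id, f.chrom, f.start, f.end, f.strand) for f in back
        ] == [(f.peptide_id, f.chrom, f.start, f.end, f.strand) for f in fragments]

    def test_minus_fragment_keeps_plus_coordinates(self, tmp_path):
        frag = self._frag(strand="-")
        write_gtf([frag], tmp_path / "m.gtf")
        cols = (tmp_path / "m.gtf").read_text().split("\t")
        assert cols[6] == "-" and int(cols[3]) < int(cols[4])


class TestLoadPeptides:
    def test_fasta_and_fastq(self, tmp_path):
        fa = tmp_path / "p.fa"
        fa.write_text(">A\nAVLLPQPPK\n>B\nGILLPQPPK\n")
        assert [p.sequence for p in load_peptides(fa)] == ["AVLLPQPPK", "GILLPQPPK"]
        fq = tmp_path / "p.fq"
        fq.write_text("@A\nAVLLPQPPK\n+\nIIIIIIIII\n")
        assert load_peptides(fq)[0].sequence == "AVLLPQPPK"

    def test_malformed_input_rejected(self, tmp_path):
        bad = tmp_path / "bad.txt"
        bad.write_text("AVLLPQPPK\n")
        with pytest.raises(ValueError):
            load_peptides(bad)
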