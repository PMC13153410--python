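"""Deterministic synthetic data with planted ground truth.

Generates a toy genome carrying provirus-like regions into which known
peptide-coding windows are planted, per-sample RNA alignments whose reads
are placed deterministically over those windows, and a machine-readable
truth set, so the whole pipeline (database build -> peptide search ->
counting -> reporting) is testable offline with exact expected answers.

The default cohort deliberately includes the three failure modes the
method must survive:

* the same peptide planted at two genomic loci (a duplicated region), with
  multi-mapping reads (NH=2) shared between the loci;
* a long peptide whose substring is also a query, producing nested
  fragments on the '-' strand;
* a near-miss window one nucleotide away from a query peptide, with an SNV
  that converts it into a true coding window for exactly one sample.

All outputs are pure functions of the seed (byte-identical reruns).  Reads
are placed at stratified deterministic positions, and per-fragment truth
counts are recomputed by independent interval-overlap arithmetic over the
placed reads, so count recovery is exact rather than statistical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
from intervaltree import IntervalTree

from ._seq import CODON_TABLE, revcomp, translate

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# deterministic reverse translation: lexicographically first codon per residue
_CODON_OF: dict[str, str] = {}
for codon in sorted(CODON_TABLE):
    aa = CODON_TABLE[codon]
    _CODON_OF.setdefault(aa, codon)

DEFAULT_READ_LEN = 50
DEFAULT_REGION_LEN = 240
DEFAULT_CONTIG_LEN = 10_000

# the default query peptide set (immunopeptidome-style 9-15mers)
DEFAULT_PEPTIDES = {
    "P1": "VILPPQPPK",
    "P2": "AVLLPQPPK",
    "P3": "GILLPQPPK",
    "PLONG": "NEAIEQVRAICLRAW",
    "PNEST": "IEQVRAICL",  # substring of PLONG at offset 3 -> nested fragment
    "PSNV": "KLIAGLIFLK",  # only reachable through the planted SNV
}


def reverse_translate(peptide: str) -> str:
    """Deterministic coding DNA for a peptide (first codon per residue)."""
    return "".join(_CODON_OF[aa] for aa in peptide)


@dataclass
class PlantedFragment:
    peptide_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    personalized_only: bool = False

    @property
    def label(self) -> str:
        return f"{self.peptide_id}|{self.chrom}:{self.start}-{self.end}|{self.strand}"


@dataclass
class TruthSet:
    peptides: dict[str, str]
    fragments: list[PlantedFragment]
    snvs: list[dict]
    counts_unique: dict[str, dict[str, int]] = field(default_factory=dict)
    counts_fractional: dict[str, dict[str, float]] = field(default_factory=dict)
    samples: list[dict] = field(default_factory=list)

    def reference_fragments(self) -> list[PlantedFragment]:
        return [f for f in self.fragments if not f.personalized_only]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "peptides": self.peptides,
                    "fragments": [vars(f) for f in self.fragments],
                    "snvs": self.snvs,
                    "counts_unique": self.counts_unique,
                    "counts_fractional": self.counts_fractional,
                    "samples": self.samples,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            peptides=d["peptides"],
            fragments=[PlantedFragment(**f) for f in d["fragments"]],
            snvs=d["snvs"],
            counts_unique=d["counts_unique"],
            counts_fractional=d["counts_fractional"],
            samples=d["samples"],
        )


def make_genome(
    n_contigs: int = 2,
    contig_len: int = DEFAULT_CONTIG_LEN,
    gc: float = 0.42,
    seed: int = 0,
) -> dict[str, str]:
    """Random genome as a dict of contig name -> sequence."""
    if contig_len < 1000:
        raise ValueError("contig_len must be >= 1 kb")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    return {
        f"chr{chr(ord('A') + i)}": "".join(
            bases[rng.choice(4, size=contig_len, p=p)]
        )
        for i in range(n_contigs)
    }


def write_genome_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    pysam.faidx(str(path))
    return path


@dataclass
class _RegionPlan:
    region_id: str
    chrom: str
    start: int
    end: int
    strand: str
    plants: list[tuple[str, int, str]]  # (peptide_id-or-raw, frag_start, frag_strand)


def plant_herv_regions(
    genome: dict[str, str],
    seed: int = 0,
    peptides: dict[str, str] | None = None,
) -> tuple[dict[str, str], list[dict], TruthSet]:
    """Edit the genome in place with planted regions; return regions + truth.

    Returns ``(edited genome, region rows, truth)`` where each region row is
    a dict with region_id/chrom/start/end/strand/sequence.  The layout is
    fixed relative to the contig grid; the surrounding sequence varies with
    the seed through ``make_genome``.
    """
    peptides = dict(peptides or DEFAULT_PEPTIDES)
    g = {name: list(seq) for name, seq in genome.items()}

    # layout: region anchor positions on the contig grid
    plans = [
        # P1 on a '+' region, forward frame
        _RegionPlan("HERV_P1", "chrA", 1001, 1240, "+", [("P1", 1101, "+")]),
        # P2 on a '+' region but reverse reading frame -> '-' fragment
        _RegionPlan("HERV_P2", "chrA", 2001, 2240, "+", [("P2", 2101, "-")]),
        # decoy: P2 with one residue off (single-nt miss), never a hit
        _RegionPlan("HERV_DECOY", "chrA", 3001, 3240, "+", []),
        # SNV target: PSNV with one residue off; the SNV restores it
        _RegionPlan("HERV_SNV", "chrA", 4001, 4240, "+", []),
        # P3 on a '-' region, fragment on the '+' genomic strand
        _RegionPlan("HERV_P3", "chrB", 1001, 1240, "-", [("P3", 1101, "+")]),
        # PLONG on a '-' region and '-' strand; PNEST nests inside it
        _RegionPlan("HERV_PLONG", "chrB", 2001, 2240, "-", [("PLONG", 2101, "-")]),
        # duplicated copy of the P1 region -> multi-mapping locus
        _RegionPlan("HERV_P1DUP", "chrB", 3001, 3240, "+", [("P1", 3101, "+")]),
    ]

    def write_plus(chrom: str, start: int, plus_seq: str) -> None:
        for i, b in enumerate(plus_seq):
            g[chrom][start - 1 + i] = b

    truth_frags: list[PlantedFragment] = []
    for plan in plans:
        for pid, frag_start, frag_strand in plan.plants:
            coding = reverse_translate(peptides[pid])
            frag_end = frag_start + len(coding) - 1
            plus_seq = coding if frag_strand == "+" else revcomp(coding)
            write_plus(plan.chrom, frag_start, plus_seq)
            truth_frags.append(
                PlantedFragment(pid, plan.chrom, frag_start, frag_end, frag_strand)
            )

    # make the duplicated region byte-identical to the P1 region
    p1 = next(p for p in plans if p.region_id == "HERV_P1")
    dup = next(p for p in plans if p.region_id == "HERV_P1DUP")
    src = "".join(g[p1.chrom][p1.start - 1 : p1.end])
    write_plus(dup.chrom, dup.start, src)
    # re-derive the duplicate's truth fragment from the copy arithmetic
    truth_frags = [f for f in truth_frags if not (f.peptide_id == "P1" and f.chrom == dup.chrom)]
    p1_frag = next(f for f in truth_frags if f.peptide_id == "P1")
    off = p1_frag.start - p1.start
    truth_frags.append(
        PlantedFragment(
            "P1", dup.chrom, dup.start + off, dup.start + off + (p1_frag.end - p1_frag.start), p1_frag.strand
        )
    )

    # nested fragment: PNEST is PLONG[3:12]; on a '-' fragment the nested
    # window sits 3*offset in from the *end*
    plong = next(f for f in truth_frags if f.peptide_id == "PLONG")
    n_off, n_len = 3, len(peptides["PNEST"])
    assert peptides["PLONG"][n_off : n_off + n_len] == peptides["PNEST"]
    truth_frags.append(
        PlantedFragment(
            "PNEST",
            plong.chrom,
            plong.end - 3 * (n_off + n_len) + 1,
            plong.end - 3 * n_off,
            "-",
        )
    )

    # decoy: P2 with A->V at residue 0 (GCA -> GTA, one nt off); exact search
    # must never hit it
    decoy = next(p for p in plans if p.region_id == "HERV_DECOY")
    decoy_coding = reverse_translate("V" + peptides["P2"][1:])
    write_plus(decoy.chrom, 3101, decoy_coding)

    # SNV target: PSNV with G5->R (GGA -> AGA); the enabling SNV is A->G at
    # the first base of that codon
    snv_plan = next(p for p in plans if p.region_id == "HERV_SNV")
    near_miss = peptides["PSNV"][:4] + "R" + peptides["PSNV"][5:]
    nm_coding = list(reverse_translate(near_miss))
    # confirm the single-nt relationship, then record the SNV
    true_coding = reverse_translate(peptides["PSNV"])
    diffs = [i for i, (a, b) in enumerate(zip(nm_coding, true_coding)) if a != b]
    assert len(diffs) == 1
    snv_frag_start = 4101
    write_plus(snv_plan.chrom, snv_frag_start, "".join(nm_coding))
    snv_pos = snv_frag_start + diffs[0]
    snvs = [
        {
            "chrom": snv_plan.chrom,
            "pos": snv_pos,
            "ref": nm_coding[diffs[0]],
            "alt": true_coding[diffs[0]],
            "enables_peptide": "PSNV",
        }
    ]
    truth_frags.append(
        PlantedFragment(
            "PSNV",
            snv_plan.chrom,
            snv_frag_start,
            snv_frag_start + len(nm_coding) - 1,
            "+",
            personalized_only=True,
        )
    )

    genome_out = {name: "".join(chars) for name, chars in g.items()}

    region_rows = []
    for plan in plans:
        plus = genome_out[plan.chrom][plan.start - 1 : plan.end]
        region_rows.append(
            {
                "region_id": plan.region_id,
                "chrom": plan.chrom,
                "start": plan.start,
                "end": plan.end,
                "strand": plan.strand,
                "sequence": plus if plan.strand == "+" else revcomp(plus),
            }
        )

    truth = TruthSet(peptides=peptides, fragments=truth_frags, snvs=snvs)
    _verify_plants(genome_out, region_rows, truth)
    return genome_out, region_rows, truth


def _verify_plants(
    genome: dict[str, str], region_rows: list[dict], truth: TruthSet
) -> None:
    """Independent scan: every query peptide occurs in the regions' six-frame
    translations exactly at the designed truth windows (reference plants), and
    nowhere else."""
    found: set[tuple[str, str, int, int, str]] = set()
    for row in region_rows:
        for frag in _scan_region(row, truth.peptides):
            found.add(frag)
    expected = {
        (f.peptide_id, f.chrom, f.start, f.end, f.strand)
        for f in truth.reference_fragments()
    }
    if found != expected:
        raise RuntimeError(
            f"fixture self-check failed: scan found {sorted(found - expected)} "
            f"unexpected / missed {sorted(expected - found)}"
        )
    # and the genome agrees with the region sequences
    for row in region_rows:
        window = genome[row["chrom"]][row["start"] - 1 : row["end"]]
        expected_seq = row["sequence"] if row["strand"] == "+" else revcomp(row["sequence"])
        if window != expected_seq:
            raise RuntimeError(f"region {row['region_id']} disagrees with genome")


def _scan_region(
    row: dict, peptides: dict[str, str]
) -> list[tuple[str, str, int, int, str]]:
    """Brute-force six-frame peptide scan of one region with inline coordinate
    arithmetic (kept independent of the database modules on purpose)."""
    out = []
    plus = row["sequence"] if row["strand"] == "+" else revcomp(row["sequence"])
    minus = revcomp(plus)
    n = len(plus)
    for pid, pep in peptides.items():
        for shift in range(3):
            fwd = translate(plus[shift:])
            pos = fwd.find(pep)
            while pos != -1:
                s = row["start"] + shift + 3 * pos
                out.append((pid, row["chrom"], s, s + 3 * len(pep) - 1, "+"))
                pos = fwd.find(pep, pos + 1)
            rev = translate(minus[shift:])
            pos = rev.find(pep)
            while pos != -1:
                e = row["end"] - shift - 3 * pos
                out.append((pid, row["chrom"], e - 3 * len(pep) + 1, e, "-"))
                pos = rev.find(pep, pos + 1)
    return out


def write_region_files(
    region_rows: list[dict], fasta_path: str | Path, bed_path: str | Path
) -> None:
    """Region sequences as FASTA plus a 6-column BED (0-based half-open)."""
    with open(fasta_path, "w") as fh:
        for row in region_rows:
            fh.write(f">{row['region_id']}\n{row['sequence']}\n")
    with open(bed_path, "w") as fh:
        for row in region_rows:
            fh.write(
                f"{row['chrom']}\t{row['start'] - 1}\t{row['end']}"
                f"\t{row['region_id']}\t0\t{row['strand']}\n"
            )


def make_snv_vcf(
    path: str | Path,
    genome: dict[str, str],
    snvs: list[dict],
    sample_id: str,
    extra_records: list[str] | None = None,
) -> Path:
    """Single-sample VCF for the planted SNVs (REF checked against the plus
    strand); ``extra_records`` lets callers append raw non-SNV lines."""
    path = Path(path)
    contigs = "".join(
        f"##contig=<ID={name},length={len(seq)}>\n" for name, seq in genome.items()
    )
    lines = [
        "##fileformat=VCFv4.2\n",
        contigs,
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n",
    ]
    for snv in snvs:
        ref_on_genome = genome[snv["chrom"]][snv["pos"] - 1]
        if ref_on_genome != snv["ref"]:
            raise ValueError(
                f"SNV REF {snv['ref']} at {snv['chrom']}:{snv['pos']} does not "
                f"match genome base {ref_on_genome}"
            )
        if snv["ref"] == snv["alt"]:
            raise ValueError("alt == ref")
        lines.append(
            f"{snv['chrom']}\t{snv['pos']}\t.\t{snv['ref']}\t{snv['alt']}"
            f"\t50\tPASS\t.\tGT\t0/1\n"
        )
    for raw in extra_records or []:
        lines.append(raw.rstrip("\n") + "\n")
    path.write_text("".join(lines))
    return path


def simulate_reads(
    genome: dict[str, str],
    truth: TruthSet,
    out_dir: str | Path,
    n_patients: int = 3,
    read_len: int = DEFAULT_READ_LEN,
    seed: int = 0,
    multimap_reads_per_sample: int = 2,
) -> TruthSet:
    """Per-sample sorted+indexed BAMs with deterministic read placement.

    Each reference fragment receives a small per-sample number of unique
    reads (deterministic function of the seed; some cells are zero), placed
    at stratified positions overlapping the fragment.  The duplicated-locus
    fragment pair additionally receives NH=2 read pairs-of-alignments, one
    alignment per locus.  Truth counts (unique-mode integers and fractional
    weights) are recomputed from the placed alignments by interval overlap
    and stored on the returned TruthSet.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed + 10_007)
    frags = truth.reference_fragments()
    for f in frags:
        if read_len > len(genome[f.chrom]):
            raise ValueError("read_len larger than contig")

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.items()],
    }
    ref_ids = {name: i for i, name in enumerate(genome)}

    # fragment interval index per chrom, for truth-count arithmetic
    trees: dict[str, IntervalTree] = {}
    for f in frags:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start - 1, f.end, f.label)

    p1_pair = sorted(
        (f for f in frags if f.peptide_id == "P1"), key=lambda f: (f.chrom, f.start)
    )

    samples = []
    truth.counts_unique = {}
    truth.counts_fractional = {}
    for p in range(1, n_patients + 1):
        for group in ("tumor", "normal"):
            sid = f"p{p}_{group}"
            samples.append(
                {
                    "sample_id": sid,
                    "patient_id": f"p{p}",
                    "group": group,
                    "bam": str(out_dir / f"{sid}.bam"),
                }
            )
    truth.samples = samples

    for sample in samples:
        sid = sample["sample_id"]
        unique_counts: dict[str, float] = {f.label: 0.0 for f in frags}
        frac_counts: dict[str, float] = {f.label: 0.0 for f in frags}
        alignments: list[tuple[int, int, int, dict]] = []  # (tid, pos0, nh, extra)

        n_read = 0
        for f in frags:
            intended = int(rng.integers(0, 6))
            lo = max(f.start - read_len, 0)  # 0-based start giving >=1bp overlap
            hi = min(f.end - 1, len(genome[f.chrom]) - read_len)
            for i in range(intended):
                if intended == 1:
                    pos0 = (lo + hi) // 2
                else:
                    pos0 = lo + round(i * (hi - lo) / (intended - 1))
                alignments.append(
                    (ref_ids[f.chrom], pos0, 1, {"name": f"{sid}.u{n_read}"})
                )
                n_read += 1
                for iv in trees[f.chrom].overlap(pos0, pos0 + read_len):
                    unique_counts[iv.data] += 1
                    frac_counts[iv.data] += 1

        # multi-mapping reads over the duplicated P1 locus pair
        if sample["group"] == "tumor" and len(p1_pair) == 2:
            fa, fb = p1_pair
            for i in range(multimap_reads_per_sample):
                off = -5 + 3 * i  # same relative offset at both loci
                pa = fa.start - 1 + off
                pb = fb.start - 1 + off
                name = f"{sid}.m{i}"
                alignments.append((ref_ids[fa.chrom], pa, 2, {"name": name}))
                alignments.append(
                    (ref_ids[fb.chrom], pb, 2, {"name": name, "secondary": True})
                )
                for chrom, pos0 in ((fa.chrom, pa), (fb.chrom, pb)):
                    for iv in trees[chrom].overlap(pos0, pos0 + read_len):
                        frac_counts[iv.data] += 0.5

        bam_path = Path(sample["bam"])
        unsorted = bam_path.with_suffix(".unsorted.bam")
        contig_names = list(genome)
        with pysam.AlignmentFile(str(unsorted), "wb", header=header) as bam:
            for tid, pos0, nh, extra in alignments:
                a = pysam.AlignedSegment()
                a.query_name = extra["name"]
                a.reference_id = tid
                a.reference_start = pos0
                a.mapping_quality = 255
                a.cigartuples = [(0, read_len)]
                a.query_sequence = genome[contig_names[tid]][pos0 : pos0 + read_len]
                a.flag = 0x100 if extra.get("secondary") else 0
                a.set_tag("NH", nh)
                bam.write(a)
        pysam.sort("-o", str(bam_path), str(unsorted))
        unsorted.unlink()
        pysam.index(str(bam_path))

        truth.counts_unique[sid] = {k: int(v) for k, v in unique_counts.items()}
        truth.counts_fractional[sid] = frac_counts
    return truth


def make_fixture_cohort(
    out_dir: str | Path,
    seed: int = 0,
    n_patients: int = 3,
    contig_len: int = DEFAULT_CONTIG_LEN,
    read_len: int = DEFAULT_READ_LEN,
) -> dict:
    """Generate the full offline test cohort under ``out_dir``.

    Writes genome FASTA (+.fai), region FASTA + BED, peptide FASTA,
    per-sample BAMs (+.bai), a manifest TSV, the enabling-SNV VCF for
    sample p1_tumor, and truth.json; returns the path map plus the TruthSet.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = make_genome(n_contigs=2, contig_len=contig_len, seed=seed)
    genome, region_rows, truth = plant_herv_regions(genome, seed=seed)

    genome_fa = write_genome_fasta(genome, out_dir / "genome.fa")
    region_fa = out_dir / "regions.fa"
    region_bed = out_dir / "regions.bed"
    write_region_files(region_rows, region_fa, region_bed)

    peptides_fa = out_dir / "peptides.fa"
    with open(peptides_fa, "w") as fh:
        for pid, seq in truth.peptides.items():
            fh.write(f">{pid}\n{seq}\n")

    truth = simulate_reads(
        genome, truth, out_dir / "bam", n_patients=n_patients,
        read_len=read_len, seed=seed,
    )

    vcf_sample = "p1_tumor"
    vcf_path = make_snv_vcf(out_dir / f"{vcf_sample}.vcf", genome, truth.snvs, vcf_sample)

    manifest_path = out_dir / "manifest.tsv"
    with open(manifest_path, "w") as fh:
        fh.write("sample_id\tpatient_id\tgroup\talignment_path\n")
        for s in truth.samples:
            fh.write(f"{s['sample_id']}\t{s['patient_id']}\t{s['group']}\t{s['bam']}\n")

    truth_path = out_dir / "truth.json"
    truth.to_json(truth_path)
    return {
        "genome_fa": genome_fa,
        "genome": genome,
        "region_fa": region_fa,
        "region_bed": region_bed,
        "peptides_fa": peptides_fa,
        "manifest": manifest_path,
        "vcf": vcf_path,
        "vcf_sample": vcf_sample,
        "truth_path": truth_path,
        "truth": truth,
    }
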