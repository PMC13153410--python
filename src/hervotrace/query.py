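"""Step 1 — trace query peptides to candidate genomic fragments.

The canonical search backend is exact substring matching of the peptide
against every ORF protein: the retained hits of the method are by
definition 100%-identity, full-length matches, which is precisely an exact
substring occurrence.  A BLASTP backend running the published permissive
parameter set is provided for compatibility; its output is filtered to
100% identity and full query length and is a subset of (normally equal
to) the exact backend.

Each hit is converted to the exact genomic interval encoding the peptide —
3x the peptide length — by offset arithmetic within the ORF placement, and
verified by translating the fragment's coding-orientation DNA back to the
peptide.  Fragments are reported in plus-strand coordinates with a strand
flag and emitted as GTF.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

from ._seq import translate, validate_peptide
from .reference_db import (
    CoordinatePlacement,
    OrfDatabase,
    placement_coding_sequence,
)

logger = logging.getLogger(__name__)

GTF_FEATURE = "HERV_fragment"
GTF_SOURCE = "hervotrace"


@dataclass(frozen=True)
class PeptideQuery:
    peptide_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_peptide(self.sequence))


@dataclass(frozen=True)
class QueryConfig:
    """Search backend configuration.

    The blastp defaults reproduce the published parameter set for short
    near-exact peptide matching; the exact backend ignores them.
    """

    backend: str = "exact"
    word_size: int = 3
    gapopen: int = 9
    gapextend: int = 1
    matrix: str = "PAM30"
    threshold: int = 16
    comp_based_stats: int = 0
    window_size: int = 15
    evalue: float = 0.05
    threads: int = 1


@dataclass(frozen=True)
class PeptideHit:
    peptide_id: str
    orf_id: str
    protein_offset: int  # 0-based amino-acid offset of the match in the ORF
    identity_pct: float = 100.0
    align_len: int = 0


@dataclass(frozen=True)
class FragmentSource:
    region_id: str
    orf_id: str
    protein_offset: int
    orf_placement: CoordinatePlacement
    provenance: str


@dataclass
class GenomicFragment:
    """The exact genomic interval (3x peptide length) encoding a peptide."""

    peptide_id: str
    chrom: str
    start: int  # 1-based inclusive, plus strand
    end: int
    strand: str
    sources: list[FragmentSource]

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def key(self) -> tuple:
        return (self.peptide_id, self.chrom, self.start, self.end, self.strand)


def load_peptides(path: str | Path) -> list[PeptideQuery]:
    """Read query peptides from FASTA or FASTQ (qualities ignored)."""
    text = Path(path).read_text()
    peptides: list[PeptideQuery] = []
    if text.lstrip().startswith("@"):  # FASTQ
        lines = [l for l in text.splitlines() if l]
        if len(lines) % 4:
            raise ValueError(f"{path}: truncated FASTQ")
        for i in range(0, len(lines), 4):
            peptides.append(PeptideQuery(lines[i][1:].split()[0], lines[i + 1]))
    else:
        name, chunks = None, []
        for line in text.splitlines():
            if line.startswith(">"):
                if name is not None:
                    peptides.append(PeptideQuery(name, "".join(chunks)))
                name, chunks = line[1:].split()[0] if line[1:].split() else "", []
            elif line.strip():
                if name is None:
                    raise ValueError(f"{path}: not FASTA/FASTQ")
                chunks.append(line.strip())
        if name is not None:
            peptides.append(PeptideQuery(name, "".join(chunks)))
    if not peptides:
        raise ValueError(f"{path}: no peptide records")
    ids = [p.peptide_id for p in peptides]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate peptide ids")
    return peptides


def find_peptide_hits(
    peptide: PeptideQuery, orf_db: OrfDatabase, config: QueryConfig | None = None
) -> list[PeptideHit]:
    """Every 100%-identity, full-length occurrence of the peptide in the db."""
    config = config or QueryConfig()
    if len(orf_db) == 0:
        raise ValueError("empty ORF database")
    if config.backend == "exact":
        hits = [
            PeptideHit(
                peptide_id=peptide.peptide_id,
                orf_id=orf.orf_id,
                protein_offset=off,
                identity_pct=100.0,
                align_len=len(peptide.sequence),
            )
            for orf, off in orf_db.search_protein(peptide.sequence)
        ]
    elif config.backend == "blastp":
        hits = _blastp_hits(peptide, orf_db, config)
    else:
        raise ValueError(f"unknown backend {config.backend!r}")
    return sorted(hits, key=lambda h: (h.orf_id, h.protein_offset))


def _blastp_hits(
    peptide: PeptideQuery, orf_db: OrfDatabase, config: QueryConfig
) -> list[PeptideHit]:
    """BLASTP backend with the published parameters, then the 100%/length filter."""
    if shutil.which("blastp") is None or shutil.which("makeblastdb") is None:
        raise RuntimeError("blastp backend requires the BLAST+ binaries on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        dbfa = tmp / "orfs.fa"
        with open(dbfa, "w") as fh:
            for orf in orf_db.iter_orfs():
                fh.write(f">{orf.orf_id}\n{orf.protein}\n")
        subprocess.run(
            ["makeblastdb", "-in", str(dbfa), "-dbtype", "prot"],
            check=True,
            capture_output=True,
        )
        qfa = tmp / "query.fa"
        qfa.write_text(f">{peptide.peptide_id}\n{peptide.sequence}\n")
        out = subprocess.run(
            [
                "blastp",
                "-query", str(qfa),
                "-db", str(dbfa),
                "-word_size", str(config.word_size),
                "-gapopen", str(config.gapopen),
                "-gapextend", str(config.gapextend),
                "-matrix", config.matrix,
                "-threshold", str(config.threshold),
                "-comp_based_stats", str(config.comp_based_stats),
                "-window_size", str(config.window_size),
                "-evalue", str(config.evalue),
                "-num_threads", str(config.threads),
                "-outfmt",
                "6 qacc sacc pident qseq length mismatch gapopen qlen qstart qend slen sstart send evalue bitscore",
            ],
            check=True,
            capture_output=True,
            text=True,
        ).stdout
    hits: list[PeptideHit] = []
    L = len(peptide.sequence)
    for line in out.splitlines():
        f = line.split("\t")
        pident, length, qstart, qend = float(f[2]), int(f[4]), int(f[8]), int(f[9])
        sstart = int(f[11])
        # retain only 100% identity over the full peptide length
        if pident == 100.0 and length == L and qstart == 1 and qend == L:
            hits.append(
                PeptideHit(
                    peptide_id=peptide.peptide_id,
                    orf_id=f[1],
                    protein_offset=sstart - 1,
                    identity_pct=pident,
                    align_len=length,
                )
            )
    return hits


def hit_to_fragments(hit: PeptideHit, orf_db: OrfDatabase) -> list[GenomicFragment]:
    """One fragment per placement of the hit ORF, translation-verified."""
    orf = orf_db.get_orf(hit.orf_id)
    L = hit.align_len or len(orf.protein) - hit.protein_offset
    peptide_seq = orf.protein[hit.protein_offset : hit.protein_offset + L]
    frags: list[GenomicFragment] = []
    for p in orf.placements:
        if p.genomic_strand == "+":
            start = p.start + 3 * hit.protein_offset
            end = start + 3 * L - 1
        else:
            end = p.end - 3 * hit.protein_offset
            start = end - 3 * L + 1
        if start < p.start or end > p.end:
            raise RuntimeError(
                f"fragment [{start},{end}] escapes ORF placement "
                f"[{p.start},{p.end}] for {hit.orf_id}"
            )
        frag_placement = CoordinatePlacement(
            chrom=p.chrom, start=start, end=end,
            genomic_strand=p.genomic_strand, assembly=p.assembly,
        )
        region = orf_db.get_region(orf.region_id)
        if orf.provenance == "reference":
            coding = placement_coding_sequence(region, frag_placement)
            if translate(coding) != peptide_seq:
                raise RuntimeError(
                    f"fragment round-trip failure for {hit.orf_id} at "
                    f"{frag_placement.chrom}:{start}-{end}"
                )
        frags.append(
            GenomicFragment(
                peptide_id=hit.peptide_id,
                chrom=p.chrom,
                start=start,
                end=end,
                strand=p.genomic_strand,
                sources=[
                    FragmentSource(
                        region_id=orf.region_id,
                        orf_id=orf.orf_id,
                        protein_offset=hit.protein_offset,
                        orf_placement=p,
                        provenance=orf.provenance,
                    )
                ],
            )
        )
    return frags


def merge_fragments(fragments: list[GenomicFragment]) -> list[GenomicFragment]:
    """Merge fragments sharing (peptide, chrom, start, end, strand)."""
    merged: dict[tuple, GenomicFragment] = {}
    for f in fragments:
        key = f.key()
        if key in merged:
            merged[key].sources.extend(f.sources)
        else:
            merged[key] = GenomicFragment(
                peptide_id=f.peptide_id, chrom=f.chrom, start=f.start,
                end=f.end, strand=f.strand, sources=list(f.sources),
            )
    out = list(merged.values())
    for f in out:
        f.sources.sort(key=lambda s: (s.region_id, s.orf_id, s.protein_offset))
    out.sort(key=lambda f: (f.peptide_id, f.chrom, f.start, f.end, f.strand))
    return out


def trace_peptides(
    peptides: list[PeptideQuery],
    orf_db: OrfDatabase,
    config: QueryConfig | None = None,
) -> list[GenomicFragment]:
    """Search all peptides and return merged, sorted fragments."""
    frags: list[GenomicFragment] = []
    for pep in peptides:
        for hit in find_peptide_hits(pep, orf_db, config):
            frags.extend(hit_to_fragments(hit, orf_db))
    return merge_fragments(frags)


# ----------------------------- GTF emission -----------------------------

def write_gtf(fragments: list[GenomicFragment], path: str | Path) -> None:
    """One GTF2.2 feature line per fragment.

    Attributes carry the peptide id, the contributing region/ORF ids, the
    whole-ORF genomic span(s), the hit span (the fragment itself) and the
    provenance of each source.
    """
    with open(path, "w") as fh:
        for f in fragments:
            attrs = [
                ("peptide_id", f.peptide_id),
                ("region_ids", ",".join(sorted({s.region_id for s in f.sources}))),
                ("orf_ids", ",".join(s.orf_id for s in f.sources)),
                (
                    "orf_span",
                    ",".join(
                        f"{s.orf_placement.chrom}:{s.orf_placement.start}-{s.orf_placement.end}"
                        for s in f.sources
                    ),
                ),
                ("hit_span", f"{f.chrom}:{f.start}-{f.end}"),
                ("provenance", ",".join(sorted({s.provenance for s in f.sources}))),
            ]
            attr_str = " ".join(f'{k} "{v}";' for k, v in attrs)
            fh.write(
                f"{f.chrom}\t{GTF_SOURCE}\t{GTF_FEATURE}\t{f.start}\t{f.end}"
                f"\t.\t{f.strand}\t.\t{attr_str}\n"
            )


def read_gtf(path: str | Path) -> list[GenomicFragment]:
    """Read back a GTF written by :func:`write_gtf` (sources are summarized:
    per-source offsets/placements are not round-tripped, ids are)."""
    frags: list[GenomicFragment] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: expected 9 GTF columns, got {len(cols)}")
            attrs: dict[str, str] = {}
            for item in cols[8].strip().split(";"):
                item = item.strip()
                if not item:
                    continue
                k, v = item.split(" ", 1)
                attrs[k] = v.strip().strip('"')
            sources = []
            orf_ids = attrs.get("orf_ids", "").split(",") if attrs.get("orf_ids") else []
            region_ids = attrs.get("region_ids", "").split(",")
            spans = attrs.get("orf_span", "").split(",") if attrs.get("orf_span") else []
            for i, oid in enumerate(orf_ids):
                span = spans[i] if i < len(spans) else None
                placement = None
                if span:
                    c, rng = span.split(":")
                    s, e = rng.split("-")
                    placement = CoordinatePlacement(
                        chrom=c, start=int(s), end=int(e),
                        genomic_strand=cols[6], assembly="",
                    )
                sources.append(
                    FragmentSource(
                        region_id=region_ids[min(i, len(region_ids) - 1)],
                        orf_id=oid,
                        protein_offset=-1,
                        orf_placement=placement,
                        provenance=attrs.get("provenance", ""),
                    )
                )
            frags.append(
                GenomicFragment(
                    peptide_id=attrs["peptide_id"],
                    chrom=cols[0],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    sources=sources,
                )
            )
    return frags


def write_hit_report(
    fragments: list[GenomicFragment], path: str | Path
) -> None:
    """TSV hit report: one row per (fragment, source)."""
    with open(path, "w") as fh:
        fh.write("peptide_id\torf_id\toffset\tchrom\tstart\tend\tstrand\tprovenance\n")
        for f in fragments:
            for s in f.sources:
                fh.write(
                    f"{f.peptide_id}\t{s.orf_id}\t{s.protein_offset}\t{f.chrom}"
                    f"\t{f.start}\t{f.end}\t{f.strand}\t{s.provenance}\n"
                )
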