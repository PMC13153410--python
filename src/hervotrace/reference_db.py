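"""Build the two local databases behind peptide tracing.

From a provirus reference (FASTA sequences + BED locations) this module
derives, for every region, the six frame translations, their maximal
stop-free open reading frames (ORFs), and for each ORF its exact placement
on the reference genome.  Because the ORFs are generated from the region
sequences themselves, the ORF -> genome localization is pure arithmetic
(frame + amino-acid offset), and every placement is verified by a
translation round-trip instead of a re-alignment step.

Coordinates at every public interface are 1-based inclusive on the
reference plus strand.  BED input (0-based half-open) is converted at the
boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from pyfaidx import Fasta

from ._seq import (
    compose_strands,
    extract_orfs,
    frame_direction,
    frame_shift,
    normalize_dna,
    revcomp,
    six_frame_translate,
    translate,
)

logger = logging.getLogger(__name__)

FORMAT_NAME = "hervotrace-orfdb"
FORMAT_VERSION = 1

REFERENCE_PROVENANCE = "reference"


@dataclass(frozen=True)
class HervRegion:
    """One provirus reference entry.

    ``sequence`` is given in *region orientation*: for a '-' region it is the
    reverse complement of the plus-strand genomic window [start, end].
    """

    region_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    sequence: str
    assembly: str = "hg19"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"region {self.region_id}: bad strand {self.strand!r}")
        if self.end < self.start:
            raise ValueError(f"region {self.region_id}: end < start")
        object.__setattr__(self, "sequence", normalize_dna(self.sequence))
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"region {self.region_id}: interval length "
                f"{self.end - self.start + 1} != sequence length {len(self.sequence)}"
            )

    def plus_strand_base(self, pos: int) -> str:
        """Reference plus-strand base at 1-based genomic position ``pos``."""
        if not self.start <= pos <= self.end:
            raise ValueError(f"position {pos} outside region {self.region_id}")
        if self.strand == "+":
            return self.sequence[pos - self.start]
        return revcomp(self.sequence[self.end - pos])


@dataclass(frozen=True)
class CoordinatePlacement:
    """A genomic interval in reference plus-strand coordinates."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    genomic_strand: str
    assembly: str = "hg19"

    def __post_init__(self) -> None:
        if self.genomic_strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.genomic_strand!r}")
        if self.end < self.start:
            raise ValueError("placement end < start")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.genomic_strand)


@dataclass
class OpenReadingFrame:
    """A stop-free translation product of one frame of a region."""

    orf_id: str
    region_id: str
    frame: str  # one of +1 +2 +3 -1 -2 -3, relative to the region sequence
    protein: str
    placements: list[CoordinatePlacement]
    provenance: str = REFERENCE_PROVENANCE

    def __post_init__(self) -> None:
        if "*" in self.protein:
            raise ValueError(f"ORF {self.orf_id}: protein contains a stop symbol")
        for p in self.placements:
            if p.span != 3 * len(self.protein):
                raise ValueError(
                    f"ORF {self.orf_id}: placement span {p.span} != "
                    f"3 x protein length {3 * len(self.protein)}"
                )


def region_offsets_to_genomic(
    region: HervRegion, off_start: int, off_end: int
) -> tuple[int, int]:
    """Map 0-based offsets in region-oriented sequence to plus-strand coords.

    ``off_start``/``off_end`` are inclusive offsets into ``region.sequence``.
    """
    if region.strand == "+":
        return region.start + off_start, region.start + off_end
    return region.end - off_end, region.end - off_start


def placement_coding_sequence(region: HervRegion, placement: CoordinatePlacement) -> str:
    """Coding-orientation DNA of ``placement``, extracted from the region.

    The plus-strand subsequence is taken from the region's own sequence and
    reverse complemented when the placement is on the '-' genomic strand.
    """
    if region.strand == "+":
        sub = region.sequence[placement.start - region.start : placement.end - region.start + 1]
    else:
        sub = revcomp(
            region.sequence[region.end - placement.end : region.end - placement.start + 1]
        )
    return sub if placement.genomic_strand == "+" else revcomp(sub)


def map_orf_to_genome(
    region: HervRegion, frame: str, frame_offset_aa: int, protein_len: int
) -> CoordinatePlacement:
    """Exact placement of an ORF extracted from ``region`` in ``frame``.

    The ORF occupies nucleotides ``[3*offset + shift, +3*len)`` of the frame's
    reading orientation; this is mirrored for reverse frames and then mapped
    through the region's own genomic strand.
    """
    n = len(region.sequence)
    shift = frame_shift(frame)
    nt_start = 3 * frame_offset_aa + shift
    nt_end = nt_start + 3 * protein_len - 1  # inclusive, in reading orientation
    if nt_end >= n:
        raise RuntimeError(
            f"ORF interval [{nt_start},{nt_end}] exceeds region {region.region_id} "
            f"length {n}: frame bookkeeping bug"
        )
    if frame_direction(frame) == "+":
        off_start, off_end = nt_start, nt_end
    else:  # reading the reverse complement: mirror into region offsets
        off_start, off_end = n - 1 - nt_end, n - 1 - nt_start
    g_start, g_end = region_offsets_to_genomic(region, off_start, off_end)
    strand = compose_strands(region.strand, frame_direction(frame))
    return CoordinatePlacement(
        chrom=region.chrom,
        start=g_start,
        end=g_end,
        genomic_strand=strand,
        assembly=region.assembly,
    )


def dedup_orfs(orfs: Iterable[OpenReadingFrame]) -> list[OpenReadingFrame]:
    """Collapse ORFs of one region/provenance that share a protein string.

    The union of placements is retained on the surviving entry; output order
    is deterministic (by first placement coordinate, then protein).
    """
    by_protein: dict[str, OpenReadingFrame] = {}
    for orf in orfs:
        prev = by_protein.get(orf.protein)
        if prev is None:
            by_protein[orf.protein] = OpenReadingFrame(
                orf_id=orf.orf_id,
                region_id=orf.region_id,
                frame=orf.frame,
                protein=orf.protein,
                placements=list(orf.placements),
                provenance=orf.provenance,
            )
        else:
            if prev.region_id != orf.region_id or prev.provenance != orf.provenance:
                raise ValueError("dedup_orfs inputs must share region and provenance")
            seen = set(p.sort_key() for p in prev.placements)
            for p in orf.placements:
                if p.sort_key() not in seen:
                    prev.placements.append(p)
                    seen.add(p.sort_key())
    out = list(by_protein.values())
    for orf in out:
        orf.placements.sort(key=lambda p: p.sort_key())
    out.sort(key=lambda o: (o.placements[0].sort_key(), o.protein))
    return out


def load_reference(
    sequences_path: str | Path,
    locations_path: str | Path,
    assembly: str = "hg19",
    permissive: bool = False,
) -> list[HervRegion]:
    """Load provirus regions from FASTA sequences + BED locations.

    The BED is 0-based half-open on disk and converted here; an optional 6th
    column provides the strand (default '+').  Records present on only one
    side, or whose interval length disagrees with the sequence length, are a
    hard error unless ``permissive`` is set (then reported and excluded).
    """
    seqs: dict[str, str] = {}
    for name, seq in _iter_fasta(sequences_path):
        rid = name.split()[0]
        if rid in seqs:
            raise ValueError(f"duplicate region id {rid!r} in {sequences_path}")
        seqs[rid] = seq

    rows: dict[str, tuple[str, int, int, str]] = {}
    with open(locations_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, bed_start, bed_end = parts[0], int(parts[1]), int(parts[2])
            rid = parts[3] if len(parts) > 3 else f"{chrom}:{bed_start}-{bed_end}"
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "+"
            rows[rid] = (chrom, bed_start + 1, bed_end, strand)

    missing_in_bed = sorted(set(seqs) - set(rows))
    missing_in_fasta = sorted(set(rows) - set(seqs))
    if missing_in_bed or missing_in_fasta:
        msg = (
            f"region id mismatch: {len(missing_in_bed)} FASTA-only "
            f"{missing_in_bed[:5]}, {len(missing_in_fasta)} BED-only "
            f"{missing_in_fasta[:5]}"
        )
        if not permissive:
            raise ValueError(msg)
        logger.warning(msg)

    regions: list[HervRegion] = []
    for rid in seqs:
        if rid not in rows:
            continue
        chrom, start, end, strand = rows[rid]
        try:
            regions.append(
                HervRegion(
                    region_id=rid,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    sequence=seqs[rid],
                    assembly=assembly,
                )
            )
        except ValueError as exc:
            if not permissive:
                raise
            logger.warning("excluding region %s: %s", rid, exc)
    return regions


def annotate_strand(
    region_sequence: str,
    genome: Fasta | dict[str, str],
    chrom: str,
    start: int,
    end: int,
    min_identity: float = 0.90,
) -> str | None:
    """Orient a region sequence against the reference plus-strand window.

    Returns '+' if the sequence matches the plus-strand window [start, end]
    (1-based inclusive) better than its reverse complement by position-wise
    identity, '-' for the converse; ``None`` when tied or when both
    orientations fall below ``min_identity``.
    """
    region_sequence = normalize_dna(region_sequence)
    if isinstance(genome, dict):
        window = genome[chrom][start - 1 : end]
    else:
        window = str(genome[chrom][start - 1 : end])
    window = normalize_dna(window)
    if len(window) != len(region_sequence):
        raise ValueError(
            f"window {chrom}:{start}-{end} length {len(window)} != "
            f"region sequence length {len(region_sequence)}"
        )
    fwd = _identity(region_sequence, window)
    rev = _identity(region_sequence, revcomp(window))
    if fwd == rev or max(fwd, rev) < min_identity:
        return None
    return "+" if fwd > rev else "-"


def _identity(a: str, b: str) -> float:
    if not a:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


class OrfDatabase:
    """The deduplicated ORF protein database plus its coordinate database.

    ``orfs`` are keyed by orf_id; substring search over protein content is
    served by :meth:`search_protein`.
    """

    def __init__(
        self,
        regions: dict[str, HervRegion],
        orfs: list[OpenReadingFrame],
        min_orf_len: int = 1,
        assembly: str = "hg19",
    ):
        self.regions = regions
        self.orfs = orfs
        self.min_orf_len = min_orf_len
        self.assembly = assembly
        self._by_id = {o.orf_id: o for o in orfs}
        if len(self._by_id) != len(orfs):
            raise ValueError("duplicate orf_ids in database")

    def __len__(self) -> int:
        return len(self.orfs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrfDatabase):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def get_orf(self, orf_id: str) -> OpenReadingFrame:
        return self._by_id[orf_id]

    def get_region(self, region_id: str) -> HervRegion:
        return self.regions[region_id]

    def iter_orfs(self) -> Iterator[OpenReadingFrame]:
        return iter(self.orfs)

    def search_protein(self, peptide: str) -> list[tuple[OpenReadingFrame, int]]:
        """All (ORF, 0-based offset) occurrences of ``peptide`` as a substring."""
        hits: list[tuple[OpenReadingFrame, int]] = []
        for orf in self.orfs:
            pos = orf.protein.find(peptide)
            while pos != -1:
                hits.append((orf, pos))
                pos = orf.protein.find(peptide, pos + 1)
        return hits

    # -- serialization: a single-file key-value store with a version header --

    def to_dict(self) -> dict:
        return {
            "format": FORMAT_NAME,
            "version": FORMAT_VERSION,
            "assembly": self.assembly,
            "min_orf_len": self.min_orf_len,
            "regions": {
                rid: {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "strand": r.strand,
                    "sequence": r.sequence,
                    "assembly": r.assembly,
                }
                for rid, r in sorted(self.regions.items())
            },
            "orfs": [
                {
                    "orf_id": o.orf_id,
                    "region_id": o.region_id,
                    "frame": o.frame,
                    "protein": o.protein,
                    "provenance": o.provenance,
                    "placements": [
                        {
                            "chrom": p.chrom,
                            "start": p.start,
                            "end": p.end,
                            "strand": p.genomic_strand,
                            "assembly": p.assembly,
                        }
                        for p in o.placements
                    ],
                }
                for o in self.orfs
            ],
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "OrfDatabase":
        if d.get("format") != FORMAT_NAME:
            raise ValueError(f"not a {FORMAT_NAME} file")
        if d.get("version") != FORMAT_VERSION:
            raise ValueError(f"unsupported database version {d.get('version')}")
        regions = {
            rid: HervRegion(
                region_id=rid,
                chrom=r["chrom"],
                start=r["start"],
                end=r["end"],
                strand=r["strand"],
                sequence=r["sequence"],
                assembly=r["assembly"],
            )
            for rid, r in d["regions"].items()
        }
        orfs = [
            OpenReadingFrame(
                orf_id=o["orf_id"],
                region_id=o["region_id"],
                frame=o["frame"],
                protein=o["protein"],
                provenance=o["provenance"],
                placements=[
                    CoordinatePlacement(
                        chrom=p["chrom"],
                        start=p["start"],
                        end=p["end"],
                        genomic_strand=p["strand"],
                        assembly=p["assembly"],
                    )
                    for p in o["placements"]
                ],
            )
            for o in d["orfs"]
        ]
        return cls(
            regions=regions,
            orfs=orfs,
            min_orf_len=d["min_orf_len"],
            assembly=d["assembly"],
        )

    @classmethod
    def load(cls, path: str | Path) -> "OrfDatabase":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def export_coordinates_tsv(self, path: str | Path) -> None:
        """TSV of the coordinate database, one row per ORF placement."""
        with open(path, "w") as fh:
            fh.write(
                "region_id\torf_id\tchrom\tstart\tend\tstrand\tframe\tprotein_length\n"
            )
            for o in self.orfs:
                for p in o.placements:
                    fh.write(
                        f"{o.region_id}\t{o.orf_id}\t{p.chrom}\t{p.start}\t{p.end}"
                        f"\t{p.genomic_strand}\t{o.frame}\t{len(o.protein)}\n"
                    )


def orfs_for_sequence(
    region: HervRegion,
    sequence: str,
    min_orf_len: int,
    provenance: str,
    id_prefix: str,
) -> list[OpenReadingFrame]:
    """Six-frame ORFs of ``sequence`` (in region orientation), deduplicated.

    ``sequence`` is the region's own sequence for the reference database, or
    an SNV-edited variant of it for a personalized database; either way the
    placements are computed against the region's genomic interval.
    """
    raw: list[OpenReadingFrame] = []
    frames = six_frame_translate(sequence)
    for frame in ("+1", "+2", "+3", "-1", "-2", "-3"):
        for protein, offset in extract_orfs(frames[frame], min_len=min_orf_len):
            placement = map_orf_to_genome(region, frame, offset, len(protein))
            orf = OpenReadingFrame(
                orf_id=f"{id_prefix}|{frame}|{offset}",
                region_id=region.region_id,
                frame=frame,
                protein=protein,
                placements=[placement],
                provenance=provenance,
            )
            raw.append(orf)
    deduped = dedup_orfs(raw)
    verify_round_trip(region, deduped, sequence)
    return deduped


def verify_round_trip(
    region: HervRegion, orfs: Iterable[OpenReadingFrame], sequence: str | None = None
) -> None:
    """Assert that every placement translates back to its ORF protein.

    For personalized ORFs the edited ``sequence`` stands in for the region's
    reference sequence when extracting the coding DNA.
    """
    src = HervRegion(
        region_id=region.region_id,
        chrom=region.chrom,
        start=region.start,
        end=region.end,
        strand=region.strand,
        sequence=sequence if sequence is not None else region.sequence,
        assembly=region.assembly,
    )
    for orf in orfs:
        for p in orf.placements:
            coding = placement_coding_sequence(src, p)
            got = translate(coding)
            if got != orf.protein:
                raise RuntimeError(
                    f"round-trip failure for {orf.orf_id} at "
                    f"{p.chrom}:{p.start}-{p.end}{p.genomic_strand}: "
                    f"{got!r} != {orf.protein!r}"
                )


def build_database(
    regions: Iterable[HervRegion],
    min_orf_len: int = 1,
    assembly: str = "hg19",
) -> OrfDatabase:
    """Build the reference ORF + coordinate database from validated regions."""
    regions = list(regions)
    if not regions:
        raise ValueError("empty region set")
    region_map: dict[str, HervRegion] = {}
    all_orfs: list[OpenReadingFrame] = []
    for region in regions:
        if region.region_id in region_map:
            raise ValueError(f"duplicate region_id {region.region_id}")
        region_map[region.region_id] = region
        orfs = orfs_for_sequence(
            region,
            region.sequence,
            min_orf_len=min_orf_len,
            provenance=REFERENCE_PROVENANCE,
            id_prefix=region.region_id,
        )
        all_orfs.extend(orfs)
    return OrfDatabase(
        regions=region_map, orfs=all_orfs, min_orf_len=min_orf_len, assembly=assembly
    )


def _iter_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name = line[1:].strip()
                chunks = []
            elif line:
                chunks.append(line.strip())
        if name is not None:
            yield name, "".join(chunks)
        elif chunks:
            raise ValueError(f"{path}: not FASTA (no '>' header)")
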