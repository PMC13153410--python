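"""Per-sample ORF databases accounting for accumulated SNVs.

A sample's VCF is intersected with the provirus regions; single-nucleotide
substitutions falling inside a region are applied jointly to one variant
haplotype of that region (one haplotype per alternate at multi-allelic
sites), and the variant sequence is re-translated in six frames.  Indels,
MNVs and symbolic alleles are counted and skipped.  Personalization is
additive: every reference ORF stays in the personalized database, and a
variant ORF identical to a reference ORF of the same region is collapsed
onto it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pysam

from .reference_db import (
    HervRegion,
    OpenReadingFrame,
    OrfDatabase,
    REFERENCE_PROVENANCE,
    orfs_for_sequence,
)

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SnvRecord:
    chrom: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str
    sample_id: str = ""
    filter_status: str = "PASS"

    def __post_init__(self) -> None:
        if self.ref_base not in _COMP or self.alt_base not in _COMP:
            raise ValueError(f"SNV at {self.chrom}:{self.pos}: bases must be A/C/G/T")
        if self.ref_base == self.alt_base:
            raise ValueError(f"SNV at {self.chrom}:{self.pos}: ref == alt")

    def descriptor(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref_base}>{self.alt_base}"


@dataclass
class PersonalizedRegion:
    region: HervRegion
    applied_variants: list[SnvRecord]
    variant_sequence: str


@dataclass
class VcfIntersection:
    """Per-region SNV assignment plus bookkeeping counters."""

    by_region: dict[str, list[SnvRecord]]
    n_records: int = 0
    n_snvs_in_regions: int = 0
    n_non_snv_skipped: int = 0
    n_outside_regions: int = 0
    n_filter_skipped: int = 0


def read_vcf_snvs(
    vcf_path: str | Path, sample_id: str, pass_only: bool = True
) -> tuple[list[SnvRecord], int, int, int]:
    """Parse a VCF into single-base SnvRecords.

    Multi-allelic records are split into one record per single-base
    alternate.  Returns ``(snvs, total_records, non_snv_skipped,
    filter_skipped)``.  With ``pass_only`` (default) only records whose
    FILTER is PASS or '.' are used.
    """
    snvs: list[SnvRecord] = []
    total = non_snv = filtered = 0
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            total += 1
            filt = list(rec.filter.keys())
            if pass_only and filt and filt != ["PASS"]:
                filtered += 1
                continue
            if not rec.alts:
                non_snv += 1
                continue
            any_snv = False
            for alt in rec.alts:
                if (
                    len(rec.ref) == 1
                    and len(alt) == 1
                    and rec.ref in _COMP
                    and alt in _COMP
                    and rec.ref != alt
                ):
                    any_snv = True
                    snvs.append(
                        SnvRecord(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref_base=rec.ref,
                            alt_base=alt,
                            sample_id=sample_id,
                            filter_status=",".join(filt) if filt else ".",
                        )
                    )
            if not any_snv:
                non_snv += 1
    return snvs, total, non_snv, filtered


def select_overlapping_snvs(
    snvs: list[SnvRecord], regions: dict[str, HervRegion]
) -> VcfIntersection:
    """Assign SNVs to the regions they fall inside.

    A VCF REF base disagreeing with the region's plus-strand base at that
    position is a hard error: it indicates a region/assembly mismatch.
    """
    inter = VcfIntersection(by_region={})
    inter.n_records = len(snvs)
    for snv in snvs:
        assigned = False
        for region in regions.values():
            if region.chrom == snv.chrom and region.start <= snv.pos <= region.end:
                expected = region.plus_strand_base(snv.pos)
                if expected != "N" and expected != snv.ref_base:
                    raise ValueError(
                        f"VCF REF {snv.ref_base} at {snv.chrom}:{snv.pos} disagrees "
                        f"with region {region.region_id} base {expected}: "
                        "region/assembly mismatch?"
                    )
                inter.by_region.setdefault(region.region_id, []).append(snv)
                assigned = True
        if assigned:
            inter.n_snvs_in_regions += 1
        else:
            inter.n_outside_regions += 1
    return inter


def apply_snvs(region: HervRegion, snvs: list[SnvRecord]) -> list[PersonalizedRegion]:
    """Apply a region's overlapping SNVs jointly to variant haplotypes.

    All SNVs are applied simultaneously; sites with several alternates give
    one haplotype per alternate (other sites held at their joint alternate).
    A '-' region substitutes the complement of the alternate at the mirrored
    offset, so the variant sequence stays in region orientation.
    """
    if not snvs:
        return []
    by_pos: dict[int, list[SnvRecord]] = {}
    for snv in snvs:
        if not region.start <= snv.pos <= region.end:
            raise ValueError(
                f"SNV {snv.descriptor()} outside region {region.region_id}"
            )
        by_pos.setdefault(snv.pos, []).append(snv)

    multi = {p: alts for p, alts in by_pos.items() if len(alts) > 1}
    single = [alts[0] for p, alts in by_pos.items() if len(alts) == 1]

    def edit(chosen: list[SnvRecord]) -> PersonalizedRegion:
        seq = list(region.sequence)
        for snv in chosen:
            if region.strand == "+":
                off, base = snv.pos - region.start, snv.alt_base
            else:
                off, base = region.end - snv.pos, _COMP[snv.alt_base]
            seq[off] = base
        return PersonalizedRegion(
            region=region,
            applied_variants=sorted(chosen, key=lambda s: (s.pos, s.alt_base)),
            variant_sequence="".join(seq),
        )

    if not multi:
        return [edit(single)]
    # one haplotype per alternate at each multi-allelic site; a cartesian
    # product over sites would explode, and the model is one accumulated
    # haplotype, so only one site varies at a time
    out: list[PersonalizedRegion] = []
    positions = sorted(multi)
    for p in positions:
        for alt in multi[p]:
            chosen = single + [alt] + [multi[q][0] for q in positions if q != p]
            out.append(edit(chosen))
    # drop duplicate haplotypes deterministically
    seen: set[str] = set()
    uniq = []
    for pr in out:
        if pr.variant_sequence not in seen:
            seen.add(pr.variant_sequence)
            uniq.append(pr)
    return uniq


def build_personalized_db(
    reference_db: OrfDatabase,
    vcf_path: str | Path,
    sample_id: str,
    pass_only: bool = True,
) -> tuple[OrfDatabase, VcfIntersection]:
    """Personalized ORF database for one sample.

    Regions with no overlapping SNVs reuse the reference entries; affected
    regions additionally contribute the six-frame ORFs of each variant
    haplotype, tagged with the sample id and applied variant descriptors.
    """
    snvs, total, non_snv, filtered = read_vcf_snvs(vcf_path, sample_id, pass_only)
    inter = select_overlapping_snvs(snvs, reference_db.regions)
    inter.n_records = total
    inter.n_non_snv_skipped = non_snv
    inter.n_filter_skipped = filtered
    if non_snv:
        logger.warning("%s: skipped %d non-SNV record(s)", sample_id, non_snv)

    orfs: list[OpenReadingFrame] = list(reference_db.iter_orfs())
    ref_proteins: dict[tuple[str, str], set[str]] = {}
    for o in reference_db.iter_orfs():
        ref_proteins.setdefault((o.region_id, o.provenance), set()).add(o.protein)

    for region_id, region_snvs in sorted(inter.by_region.items()):
        region = reference_db.get_region(region_id)
        for i, pr in enumerate(apply_snvs(region, region_snvs)):
            variants = ",".join(s.descriptor() for s in pr.applied_variants)
            provenance = f"{sample_id}:{variants}"
            var_orfs = orfs_for_sequence(
                region,
                pr.variant_sequence,
                min_orf_len=reference_db.min_orf_len,
                provenance=provenance,
                id_prefix=f"{region_id}|{sample_id}.{i}",
            )
            ref_set = ref_proteins.get((region_id, REFERENCE_PROVENANCE), set())
            for orf in var_orfs:
                # variant ORFs identical to a reference ORF of the same
                # region collapse onto the reference entry
                if orf.protein not in ref_set:
                    orfs.append(orf)

    db = OrfDatabase(
        regions=dict(reference_db.regions),
        orfs=orfs,
        min_orf_len=reference_db.min_orf_len,
        assembly=reference_db.assembly,
    )
    return db, inter
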