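"""Step 3 — summary tables with validation-ready sequences, and heatmaps.

Validation-ready sequences give the genomic DNA context of each fragment
in *coding orientation*: the window (fragment plus flanks) is extracted
from the reference plus strand and reverse complemented in full when the
fragment lies on the '-' strand, so the peptide-coding subsequence always
reads in frame left to right.  The coding part is demarcated both as a
separate column and in a bracketed single-string form ``UP[CODING]DOWN``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
import seaborn as sns
from pyfaidx import Fasta

from ._seq import revcomp, translate
from .query import GenomicFragment
from .quantify import (
    NO_READ,
    FragmentCountMatrix,
    MostExpressedRecord,
    SampleManifest,
    parse_fragment_label,
)

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 60

HEATMAP_KINDS = (
    "peptides_by_group",  # target peptides x tumor/normal groups
    "fragments_by_group",  # fragments x tumor/normal groups, per peptide
    "fragments_by_sample",  # fragments x individual samples, per peptide
)


@dataclass(frozen=True)
class ValidationSequence:
    fragment_label: str
    upstream: str
    coding: str
    downstream: str
    coding_strand: str  # fragment strand; '-' means the window was flipped

    @property
    def annotated(self) -> str:
        return f"{self.upstream}[{self.coding}]{self.downstream}"

    @property
    def window(self) -> str:
        return self.upstream + self.coding + self.downstream


def validation_sequence(
    fragment: GenomicFragment,
    genome: Fasta | dict[str, str],
    flank: int = DEFAULT_FLANK,
) -> ValidationSequence:
    """Extract the fragment's DNA context in coding orientation.

    The window is clipped at contig bounds (no padding); a fragment lying
    beyond the contig end is an error.
    """
    if isinstance(genome, dict):
        contig = genome[fragment.chrom]
        contig_len = len(contig)
        fetch = lambda s, e: contig[s:e]  # 0-based half-open
    else:
        rec = genome[fragment.chrom]
        contig_len = len(rec)
        fetch = lambda s, e: str(rec[s:e])
    if fragment.end > contig_len or fragment.start < 1:
        raise ValueError(
            f"fragment {fragment.label} beyond contig bounds (len {contig_len})"
        )
    up_start = max(fragment.start - 1 - flank, 0)
    down_end = min(fragment.end + flank, contig_len)
    upstream = fetch(up_start, fragment.start - 1).upper()
    coding = fetch(fragment.start - 1, fragment.end).upper()
    downstream = fetch(fragment.end, down_end).upper()
    if fragment.strand == "-":
        upstream, coding, downstream = (
            revcomp(downstream),
            revcomp(coding),
            revcomp(upstream),
        )
    vs = ValidationSequence(
        fragment_label=f"{fragment.chrom}:{fragment.start}-{fragment.end}",
        upstream=upstream,
        coding=coding,
        downstream=downstream,
        coding_strand=fragment.strand,
    )
    return vs


def _check_coding(vs: ValidationSequence, peptide_seq: str | None) -> None:
    if peptide_seq is not None and translate(vs.coding) != peptide_seq:
        raise RuntimeError(
            f"validation sequence for {vs.fragment_label} translates to "
            f"{translate(vs.coding)!r}, expected {peptide_seq!r}"
        )


def build_summary_tables(
    matrix: FragmentCountMatrix,
    aggregated: pd.DataFrame,
    tissue_records: list[MostExpressedRecord],
    per_sample: pd.DataFrame,
    fragments: list[GenomicFragment],
    genome: Fasta | dict[str, str],
    out_dir: str | Path,
    peptide_sequences: dict[str, str] | None = None,
    flank: int = DEFAULT_FLANK,
    drop_zero: bool = False,
) -> dict[str, Path]:
    """Write the three summary TSVs; returns kind -> path.

    (1) every (fragment, sample) count with validation-ready sequences;
    (2) the most expressed fragment per peptide at the tissue level;
    (3) the most expressed fragment per peptide per sample ('no read' cells).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    peptide_sequences = peptide_sequences or {}
    frag_by_label = {
        f"{f.peptide_id}|{f.chrom}:{f.start}-{f.end}|{f.strand}": f for f in fragments
    }
    valseqs: dict[str, ValidationSequence] = {}
    for label, f in frag_by_label.items():
        vs = validation_sequence(f, genome, flank=flank)
        _check_coding(vs, peptide_sequences.get(f.peptide_id))
        valseqs[label] = vs

    fmt = (lambda v: f"{v:.2f}") if matrix.mode.fractional else (lambda v: f"{int(round(v))}")

    # table 1: per fragment x sample
    rows1 = []
    for label in matrix.counts.index:
        pep, chrom, s, e, strand = parse_fragment_label(label)
        if drop_zero and matrix.counts.loc[label].sum() == 0:
            continue
        vs = valseqs.get(label)
        for sid in matrix.counts.columns:
            rows1.append(
                {
                    "peptide_id": pep,
                    "peptide": peptide_sequences.get(pep, ""),
                    "fragment": f"{chrom}:{s}-{e}",
                    "strand": strand,
                    "sample_id": sid,
                    "reads": fmt(matrix.counts.loc[label, sid]),
                    "coding_sequence": vs.coding if vs else "",
                    "validation_ready_sequence": vs.annotated if vs else "",
                }
            )
    t1 = out_dir / "summary_all_samples.tsv"
    pd.DataFrame(
        rows1,
        columns=[
            "peptide_id", "peptide", "fragment", "strand", "sample_id",
            "reads", "coding_sequence", "validation_ready_sequence",
        ],
    ).to_csv(t1, sep="\t", index=False)

    # table 2: most expressed per peptide, tissue level
    rows2 = []
    for rec in tissue_records:
        vs = None
        if rec.fragment != NO_READ:
            label = f"{rec.peptide_id}|{rec.fragment}|{rec.strand}"
            vs = valseqs.get(label)
        rows2.append(
            {
                "peptide_id": rec.peptide_id,
                "peptide": peptide_sequences.get(rec.peptide_id, ""),
                "herv_region": rec.fragment,
                "tumor_reads": fmt(rec.tumor_reads),
                "total_reads": fmt(rec.total_reads),
                "strand": rec.strand,
                "coding_sequence": vs.coding if vs else "",
                "validation_ready_sequence": vs.annotated if vs else "",
            }
        )
    t2 = out_dir / "summary_most_expressed_tissue.tsv"
    pd.DataFrame(
        rows2,
        columns=[
            "peptide_id", "peptide", "herv_region", "tumor_reads",
            "total_reads", "strand", "coding_sequence",
            "validation_ready_sequence",
        ],
    ).to_csv(t2, sep="\t", index=False)

    # table 3: most expressed per peptide per sample
    t3 = out_dir / "summary_most_expressed_per_sample.tsv"
    per_sample.to_csv(t3, sep="\t")
    return {"per_fragment_all_samples": t1, "most_expressed_tissue": t2,
            "most_expressed_per_sample": t3}


def _group_sums(matrix: FragmentCountMatrix, manifest: SampleManifest) -> pd.DataFrame:
    tumor = [s for s in matrix.counts.columns if manifest.group_of(s) == "tumor"]
    normal = [s for s in matrix.counts.columns if manifest.group_of(s) == "normal"]
    return pd.DataFrame(
        {
            "tumor": matrix.counts[tumor].sum(axis=1),
            "normal": matrix.counts[normal].sum(axis=1),
        }
    )


def heatmap_data(
    kind: str,
    matrix: FragmentCountMatrix,
    manifest: SampleManifest,
    peptide_id: str | None = None,
    drop_zero: bool = False,
) -> pd.DataFrame:
    """Assemble the matrix behind one of the three heatmap layouts."""
    if kind not in HEATMAP_KINDS:
        raise ValueError(f"kind must be one of {HEATMAP_KINDS}")
    if kind == "peptides_by_group":
        sums = _group_sums(matrix, manifest)
        sums["peptide"] = [parse_fragment_label(l)[0] for l in sums.index]
        data = sums.groupby("peptide")[["tumor", "normal"]].sum()
    else:
        if peptide_id is None:
            raise ValueError(f"{kind} heatmap needs a peptide_id")
        rows = [
            l for l in matrix.counts.index
            if parse_fragment_label(l)[0] == peptide_id
        ]
        labels = {l: parse_fragment_label(l)[1] + ":" +
                  f"{parse_fragment_label(l)[2]}-{parse_fragment_label(l)[3]}"
                  for l in rows}
        if kind == "fragments_by_group":
            data = _group_sums(matrix, manifest).loc[rows]
        else:
            data = matrix.counts.loc[rows]
        data = data.rename(index=labels)
    if drop_zero:
        data = data.loc[data.sum(axis=1) > 0]
    return data


def render_heatmap(
    kind: str,
    matrix: FragmentCountMatrix,
    manifest: SampleManifest,
    out_path: str | Path,
    peptide_id: str | None = None,
    drop_zero: bool = False,
) -> Path | None:
    """Render one heatmap; darker color means more reads; counts annotated.

    Returns the written path, or None (with a warning) when nothing is left
    to plot after zero-dropping.
    """
    data = heatmap_data(kind, matrix, manifest, peptide_id, drop_zero)
    if data.empty:
        logger.warning("heatmap %s: empty after drop_zero, skipped", kind)
        return None
    fig, ax = plt.subplots(
        figsize=(max(4, 0.9 * data.shape[1] + 2), max(3, 0.5 * data.shape[0] + 1.5))
    )
    fmt = ".2f" if matrix.mode.fractional else ".0f"
    sns.heatmap(
        data.astype(float), ax=ax, cmap="Reds", annot=True, fmt=fmt,
        cbar_kws={"label": "reads"},
    )
    title = kind if peptide_id is None else f"{kind} ({peptide_id})"
    ax.set_title(title)
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
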