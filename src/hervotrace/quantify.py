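"""Step 2 — count RNA-seq alignments over candidate fragments.

Counting follows featureCounts semantics with one deliberate difference:
an alignment is assigned to *every* fragment it overlaps by at least
``min_overlap_bp`` aligned bases (strand-agnostic), because candidate
fragments routinely nest and overlap and a largest-overlap disambiguation
would silently zero nested fragments.

Multi-mapping is a user choice: by default only unique alignments count
(primary records with NH absent or NH==1, weight 1); with fractional
counting on, every alignment of a read — secondary records included —
contributes weight 1/NH.
"""

from __future__ import annotations

import json
import logging
import uuid
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from .query import GenomicFragment

logger = logging.getLogger(__name__)

NO_READ = "no read"


@dataclass(frozen=True)
class CountingMode:
    count_multimapped: bool = False
    fractional: bool = False
    count_overlapping_features: bool = True  # fixed true; kept for metadata
    min_overlap_bp: int = 1
    mapq_min: int = 0
    template_mode: bool = False  # count a read pair once if either mate overlaps

    def __post_init__(self) -> None:
        if self.fractional and not self.count_multimapped:
            raise ValueError("fractional counting implies count_multimapped")
        if self.min_overlap_bp < 1:
            raise ValueError("min_overlap_bp must be >= 1")


@dataclass
class SampleManifest:
    """Rows of (sample_id, patient_id, group in {tumor, normal}, path)."""

    rows: list[tuple[str, str, str, str]]

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_ids in manifest")
        for sid, _, group, _ in self.rows:
            if group not in ("tumor", "normal"):
                raise ValueError(f"sample {sid}: group must be tumor or normal")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleManifest":
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if i == 0 and parts[0] == "sample_id":
                    continue
                if len(parts) < 4:
                    raise ValueError(f"{path}: manifest rows need 4 columns")
                rows.append((parts[0], parts[1], parts[2], parts[3]))
        return cls(rows)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tpatient_id\tgroup\talignment_path\n")
            for r in self.rows:
                fh.write("\t".join(r) + "\n")

    @property
    def sample_ids(self) -> list[str]:
        return [r[0] for r in self.rows]

    def group_of(self, sample_id: str) -> str:
        for sid, _, group, _ in self.rows:
            if sid == sample_id:
                return group
        raise KeyError(f"sample {sample_id!r} missing from manifest")


def fragment_label(f: GenomicFragment) -> str:
    return f"{f.peptide_id}|{f.chrom}:{f.start}-{f.end}|{f.strand}"


def parse_fragment_label(label: str) -> tuple[str, str, int, int, str]:
    peptide_id, span, strand = label.rsplit("|", 2)
    chrom, rng = span.rsplit(":", 1)
    s, e = rng.split("-")
    return peptide_id, chrom, int(s), int(e), strand


def count_fragment_reads(
    alignment_file: str | Path,
    fragments: list[GenomicFragment],
    mode: CountingMode | None = None,
) -> dict[str, float]:
    """Per-fragment counts for one coordinate-sorted, indexed BAM."""
    mode = mode or CountingMode()
    counts: dict[str, float] = {fragment_label(f): 0.0 for f in fragments}
    path = Path(alignment_file)
    if not (
        path.with_suffix(path.suffix + ".bai").exists()
        or path.with_name(path.stem + ".bai").exists()
    ):
        raise FileNotFoundError(f"missing BAM index for {path}")
    with pysam.AlignmentFile(str(path), "rb") as bam:
        refs = set(bam.references)
        bad = sorted({f.chrom for f in fragments} - refs)
        if bad:
            raise ValueError(
                f"chromosome naming mismatch: fragments use {bad} but the BAM "
                f"has {sorted(refs)[:10]}"
            )
        seen_templates: dict[str, set[str]] = {fragment_label(f): set() for f in fragments}
        for f in fragments:
            label = fragment_label(f)
            for aln in bam.fetch(f.chrom, f.start - 1, f.end):
                w = _alignment_weight(aln, mode)
                if w == 0.0:
                    continue
                if aln.get_overlap(f.start - 1, f.end) < mode.min_overlap_bp:
                    continue
                if mode.template_mode:
                    if aln.query_name in seen_templates[label]:
                        continue
                    seen_templates[label].add(aln.query_name)
                counts[label] += w
    if not mode.fractional:
        counts = {k: float(round(v)) for k, v in counts.items()}
    return counts


def _alignment_weight(aln: pysam.AlignedSegment, mode: CountingMode) -> float:
    if aln.is_unmapped or aln.mapping_quality < mode.mapq_min:
        return 0.0
    nh = aln.get_tag("NH") if aln.has_tag("NH") else 1
    if not mode.count_multimapped:
        # unique reads only: primary alignment with a single reported hit
        if aln.is_secondary or aln.is_supplementary or nh > 1:
            return 0.0
        return 1.0
    if mode.fractional:
        return 1.0 / max(nh, 1)
    # count multimapped, unweighted: every alignment record counts 1
    return 1.0


@dataclass
class FragmentCountMatrix:
    """fragment x sample matrix of (possibly fractional) read counts."""

    counts: pd.DataFrame  # index: fragment labels; columns: sample_ids
    mode: CountingMode
    assigned_totals: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if not self.mode.fractional:
            resid = (self.counts.values - self.counts.values.round()).max(initial=0)
            if resid > 1e-9:
                raise ValueError("non-integer counts without fractional mode")

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        fmt = "%.2f" if self.mode.fractional else "%d"
        out.index.name = "fragment"
        out.to_csv(path, sep="\t", float_format=fmt)

    @classmethod
    def from_tsv(cls, path: str | Path, mode: CountingMode) -> "FragmentCountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df.astype(float), mode=mode)


def merge_matrices(parts: list[FragmentCountMatrix]) -> FragmentCountMatrix:
    """Merge partial count matrices from separate invocations.

    Fragment sets must agree; duplicate sample ids across partials are an
    error.  Column order is deterministic (sorted sample id).
    """
    if not parts:
        raise ValueError("nothing to merge")
    all_samples: list[str] = []
    for p in parts:
        all_samples.extend(p.counts.columns)
    dupes = {s for s in all_samples if all_samples.count(s) > 1}
    if dupes:
        raise ValueError(f"duplicate sample_id across partial results: {sorted(dupes)}")
    base_index = parts[0].counts.index
    for p in parts[1:]:
        if not p.counts.index.equals(base_index):
            raise ValueError("partial results disagree on the fragment set")
    merged = pd.concat([p.counts for p in parts], axis=1)
    merged = merged[sorted(merged.columns)]
    totals: dict[str, float] = {}
    for p in parts:
        totals.update(p.assigned_totals)
    return FragmentCountMatrix(counts=merged, mode=parts[0].mode, assigned_totals=totals)


def run_quantification_jobs(
    manifest: SampleManifest,
    fragments: list[GenomicFragment],
    mode: CountingMode | None = None,
    workers: int = 1,
    task_dir: str | Path | None = None,
    task_id: str | None = None,
) -> tuple[FragmentCountMatrix, str]:
    """One counting job per sample, at most ``workers`` concurrent.

    The merged matrix is identical for any worker count; a task id resolves
    to per-sample status (JSON under ``task_dir`` when given).
    """
    mode = mode or CountingMode()
    task_id = task_id or uuid.uuid4().hex[:12]
    status: dict[str, dict] = {
        sid: {"state": "pending"} for sid in manifest.sample_ids
    }

    def job(row: tuple[str, str, str, str]) -> tuple[str, dict[str, float] | None, str | None]:
        sid, _, _, path = row
        try:
            return sid, count_fragment_reads(path, fragments, mode), None
        except Exception as exc:  # failed sample withheld, not fatal
            return sid, None, str(exc)

    with ThreadPoolExecutor(max_workers=max(workers, 1)) as pool:
        results = list(pool.map(job, manifest.rows))

    columns: dict[str, dict[str, float]] = {}
    for sid, counts, err in results:
        if err is None:
            columns[sid] = counts
            status[sid] = {"state": "done"}
        else:
            status[sid] = {"state": "failed", "error": err}
            logger.error("sample %s failed: %s", sid, err)

    labels = [fragment_label(f) for f in fragments]
    df = pd.DataFrame(
        {sid: [columns[sid][l] for l in labels] for sid in manifest.sample_ids if sid in columns},
        index=labels,
        dtype=float,
    )
    matrix = FragmentCountMatrix(
        counts=df,
        mode=mode,
        assigned_totals={sid: float(df[sid].sum()) for sid in df.columns},
    )
    if task_dir is not None:
        task_dir = Path(task_dir)
        task_dir.mkdir(parents=True, exist_ok=True)
        with open(task_dir / f"{task_id}.json", "w") as fh:
            json.dump({"task_id": task_id, "samples": status}, fh, indent=2)
    return matrix, task_id


def task_status(task_dir: str | Path, task_id: str) -> dict:
    path = Path(task_dir) / f"{task_id}.json"
    if not path.exists():
        raise KeyError(f"unknown task_id {task_id!r}")
    with open(path) as fh:
        return json.load(fh)


def aggregate_cohort(
    matrix: FragmentCountMatrix, manifest: SampleManifest
) -> pd.DataFrame:
    """Per-fragment (tumor_reads, normal_reads, total_reads) group sums."""
    for sid in matrix.counts.columns:
        manifest.group_of(sid)  # raises on missing sample
    tumor = [s for s in matrix.counts.columns if manifest.group_of(s) == "tumor"]
    normal = [s for s in matrix.counts.columns if manifest.group_of(s) == "normal"]
    out = pd.DataFrame(index=matrix.counts.index)
    out["tumor_reads"] = matrix.counts[tumor].sum(axis=1)
    out["normal_reads"] = matrix.counts[normal].sum(axis=1)
    out["total_reads"] = out["tumor_reads"] + out["normal_reads"]
    return out


@dataclass(frozen=True)
class MostExpressedRecord:
    peptide_id: str
    fragment: str  # "chrom:start-end" or NO_READ
    tumor_reads: float
    normal_reads: float
    total_reads: float
    strand: str


def _tie_key(label: str) -> tuple:
    _, chrom, start, end, strand = parse_fragment_label(label)
    return (chrom, start, end, strand)


def most_expressed_tissue(
    aggregated: pd.DataFrame, rank_by: str = "total"
) -> list[MostExpressedRecord]:
    """Per peptide, the fragment maximizing total (or tumor) reads.

    Ties break by (chrom, start, end, strand); all-zero peptides yield a
    'no read' record.
    """
    if rank_by not in ("total", "tumor"):
        raise ValueError("rank_by must be 'total' or 'tumor'")
    col = "total_reads" if rank_by == "total" else "tumor_reads"
    records: list[MostExpressedRecord] = []
    peptides = sorted({parse_fragment_label(l)[0] for l in aggregated.index})
    for pep in peptides:
        rows = [l for l in aggregated.index if parse_fragment_label(l)[0] == pep]
        best = min(rows, key=lambda l: (-aggregated.loc[l, col], _tie_key(l)))
        if aggregated.loc[rows, "total_reads"].max() == 0:
            records.append(MostExpressedRecord(pep, NO_READ, 0.0, 0.0, 0.0, "."))
            continue
        _, chrom, s, e, strand = parse_fragment_label(best)
        records.append(
            MostExpressedRecord(
                peptide_id=pep,
                fragment=f"{chrom}:{s}-{e}",
                tumor_reads=float(aggregated.loc[best, "tumor_reads"]),
                normal_reads=float(aggregated.loc[best, "normal_reads"]),
                total_reads=float(aggregated.loc[best, "total_reads"]),
                strand=strand,
            )
        )
    return records


def most_expressed_per_sample(matrix: FragmentCountMatrix) -> pd.DataFrame:
    """peptide x sample table of argmax fragment labels, or 'no read'."""
    peptides = sorted({parse_fragment_label(l)[0] for l in matrix.counts.index})
    out = pd.DataFrame(index=peptides, columns=matrix.counts.columns, dtype=object)
    for pep in peptides:
        rows = [l for l in matrix.counts.index if parse_fragment_label(l)[0] == pep]
        for sid in matrix.counts.columns:
            col = matrix.counts.loc[rows, sid]
            if col.max() == 0:
                out.loc[pep, sid] = NO_READ
            else:
                best = min(rows, key=lambda l: (-col[l], _tie_key(l)))
                _, chrom, s, e, _ = parse_fragment_label(best)
                out.loc[pep, sid] = f"{chrom}:{s}-{e}"
    out.index.name = "peptide_id"
    return out
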