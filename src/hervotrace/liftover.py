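"""Interval liftover through UCSC chain files.

An interval is lifted only when it maps through a single aligned chain
block (no split across blocks, no gap inside the interval); anything else
is rejected with a reason, never silently dropped.  This conservative rule
is appropriate for peptide-coding fragments, whose biological meaning does
not survive being broken across an alignment gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .reference_db import CoordinatePlacement
from ._seq import compose_strands


@dataclass(frozen=True)
class AlignedBlock:
    """One gapless aligned block of a chain, 0-based half-open, both sides
    in chain-local (strand-relative) coordinates."""

    t_start: int
    t_end: int
    q_start: int
    q_end: int


@dataclass
class Chain:
    score: int
    t_name: str
    t_size: int
    t_strand: str
    q_name: str
    q_size: int
    q_strand: str
    blocks: list[AlignedBlock]


@dataclass(frozen=True)
class LiftRejection:
    reason: str  # "unmapped" or "split"
    placement: CoordinatePlacement


class ChainMap:
    """Ordered alignment blocks mapping source intervals to a target assembly."""

    def __init__(self, chains: list[Chain], source_assembly: str, target_assembly: str):
        self.chains = chains
        self.source_assembly = source_assembly
        self.target_assembly = target_assembly
        self._by_target_chrom: dict[str, list[Chain]] = {}
        for c in chains:
            self._validate_blocks(c)
            self._by_target_chrom.setdefault(c.t_name, []).append(c)

    @staticmethod
    def _validate_blocks(chain: Chain) -> None:
        prev_end = -1
        for b in chain.blocks:
            if b.t_start < prev_end:
                raise ValueError(
                    f"chain {chain.t_name}->{chain.q_name}: blocks overlap or unsorted"
                )
            if b.t_end - b.t_start != b.q_end - b.q_start:
                raise ValueError("aligned block with unequal side lengths")
            prev_end = b.t_end

    @classmethod
    def from_file(
        cls, path: str | Path, source_assembly: str, target_assembly: str
    ) -> "ChainMap":
        """Parse a UCSC chain file.

        Chain convention: the *target* (t) side is the source assembly being
        lifted from, the *query* (q) side the assembly being lifted to —
        matching UCSC liftOver chain files named source-to-target.
        """
        chains: list[Chain] = []
        with open(path) as fh:
            header: list[str] | None = None
            t_off = q_off = 0
            blocks: list[AlignedBlock] = []
            for raw in fh:
                line = raw.strip()
                if line.startswith("#"):
                    continue
                if line.startswith("chain"):
                    if header is not None:
                        chains.append(_finish_chain(header, blocks))
                    header = line.split()
                    t_off = int(header[5])
                    q_off = int(header[10])
                    blocks = []
                elif line and header is not None:
                    parts = [int(x) for x in line.split()]
                    size = parts[0]
                    blocks.append(
                        AlignedBlock(t_off, t_off + size, q_off, q_off + size)
                    )
                    if len(parts) == 3:
                        t_off += size + parts[1]
                        q_off += size + parts[2]
            if header is not None:
                chains.append(_finish_chain(header, blocks))
        return cls(chains, source_assembly, target_assembly)

    def lift(
        self, placement: CoordinatePlacement
    ) -> CoordinatePlacement | LiftRejection:
        """Lift one placement; returns the lifted placement or a rejection."""
        if placement.assembly != self.source_assembly:
            raise ValueError(
                f"placement assembly {placement.assembly!r} != chain source "
                f"{self.source_assembly!r}"
            )
        s0, e0 = placement.start - 1, placement.end  # 0-based half-open
        overlapped = False
        for chain in self._by_target_chrom.get(placement.chrom, []):
            if chain.t_strand != "+":
                raise ValueError("chain files always give the source side on '+'")
            for b in chain.blocks:
                if b.t_end <= s0 or b.t_start >= e0:
                    continue
                overlapped = True
                if b.t_start <= s0 and e0 <= b.t_end:
                    off = s0 - b.t_start
                    q_s = b.q_start + off
                    q_e = q_s + (e0 - s0)
                    if chain.q_strand == "-":
                        q_s, q_e = chain.q_size - q_e, chain.q_size - q_s
                    return CoordinatePlacement(
                        chrom=chain.q_name,
                        start=q_s + 1,
                        end=q_e,
                        genomic_strand=compose_strands(
                            placement.genomic_strand, chain.q_strand
                        ),
                        assembly=self.target_assembly,
                    )
        return LiftRejection("split" if overlapped else "unmapped", placement)


def _finish_chain(header: list[str], blocks: list[AlignedBlock]) -> Chain:
    return Chain(
        score=int(header[1]),
        t_name=header[2],
        t_size=int(header[3]),
        t_strand=header[4],
        q_name=header[7],
        q_size=int(header[8]),
        q_strand=header[9],
        blocks=blocks,
    )


def lift_interval(
    placement: CoordinatePlacement, chain_map: ChainMap
) -> CoordinatePlacement | LiftRejection:
    """Functional wrapper around :meth:`ChainMap.lift`."""
    return chain_map.lift(placement)
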