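"""Synteny-based placement of unmapped sequences.

A transcript (or any unmapped sequence) that resolves to a unique
single-chromosome anchor in a comparison genome can be assigned a putative
linkage-map position whenever its bp coordinate falls inside the genome
span of a shared-synteny block with more than two mapped loci: the pair of
block anchors bracketing the transcript on the bp axis defines the smallest
cM interval the block supports, and those two loci are recorded as the left
and right flanking markers. A transcript landing exactly on an anchor gets
a zero-width interval at that anchor's position.

Placements are produced per supporting comparison species;
:func:`reconcile_across_species` consolidates them per transcript.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import ValidationError
from .homology import Anchor
from .synteny import SyntenyBlock

#: a block must hold more than two mapped loci to support a placement
MIN_PLACEMENT_LOCI = 3


@dataclass(frozen=True)
class Placement:
    """One transcript placed into one block of one comparison species."""

    query_id: str
    species: str
    block_id: str
    lg_id: str
    interval_cM: tuple[float, float]
    left_flank: str
    right_flank: str
    bp: int
    status: str  # "interval" or "zero-width"

    def __post_init__(self) -> None:
        if self.interval_cM[0] > self.interval_cM[1]:
            raise ValidationError(
                f"placement {self.query_id!r}: inverted cM interval"
            )


@dataclass(frozen=True)
class Unplaced:
    """A transcript anchor that could not be placed, with the reason."""

    query_id: str
    species: str
    reason: str  # "outside all blocks" | "block too small"


@dataclass(frozen=True)
class ConsolidatedPlacement:
    """Per-transcript consolidation of placements across species."""

    query_id: str
    flag: str  # "consistent" | "inconsistent-interval" | "conflict"
    lg_id: Optional[str]
    interval_cM: Optional[tuple[float, float]]
    n_supporting: int


@dataclass(frozen=True)
class PlacementSummary:
    n_transcripts: int
    n_placed: int
    percent_placed: float


def _bracket(block: SyntenyBlock, bp: int) -> tuple[Anchor, Anchor]:
    """Adjacent block anchors bracketing ``bp`` on the genome axis."""
    members = sorted(block.anchors, key=lambda a: (a.bp, a.cm, a.locus_id))
    for left, right in zip(members, members[1:]):
        if left.bp <= bp <= right.bp:
            return left, right
    raise ValidationError(  # caller guarantees bp inside the span
        f"bp {bp} outside block {block.block_id} span {block.genome_span_bp}"
    )


def place_transcripts(
    transcript_anchors: Iterable[Anchor],
    blocks: Sequence[SyntenyBlock],
    min_block_loci: int = MIN_PLACEMENT_LOCI,
) -> tuple[list[Placement], list[Unplaced]]:
    """Place unmapped anchors into shared-synteny blocks.

    A transcript is placed via every block of its species whose genome span
    contains its bp and whose locus count is at least ``min_block_loci``
    (default 3, i.e. more than two mapped loci). Overlapping blocks from
    different linkage groups therefore yield one placement each; the
    ambiguity is surfaced to :func:`reconcile_across_species` rather than
    silently resolved. Deterministic and independent of input order.
    """
    by_species: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        by_species.setdefault(b.species, []).append(b)

    placements: list[Placement] = []
    unplaced: list[Unplaced] = []
    for t in sorted(transcript_anchors, key=lambda a: (a.locus_id, a.species)):
        candidates = [
            b
            for b in by_species.get(t.species, [])
            if b.chromosome == t.chromosome and b.contains_bp(t.bp)
        ]
        usable = [b for b in candidates if b.n_loci >= min_block_loci]
        if not candidates:
            unplaced.append(Unplaced(t.locus_id, t.species, "outside all blocks"))
            continue
        if not usable:
            unplaced.append(Unplaced(t.locus_id, t.species, "block too small"))
            continue
        for b in sorted(usable, key=lambda b: b.block_id):
            exact = [a for a in b.anchors if a.bp == t.bp]
            if exact:
                at = min(exact, key=lambda a: (a.cm, a.locus_id))
                placements.append(
                    Placement(
                        query_id=t.locus_id,
                        species=t.species,
                        block_id=b.block_id,
                        lg_id=b.lg_id,
                        interval_cM=(at.cm, at.cm),
                        left_flank=at.locus_id,
                        right_flank=at.locus_id,
                        bp=t.bp,
                        status="zero-width",
                    )
                )
                continue
            left, right = _bracket(b, t.bp)
            lo, hi = sorted((left, right), key=lambda a: (a.cm, a.bp, a.locus_id))
            placements.append(
                Placement(
                    query_id=t.locus_id,
                    species=t.species,
                    block_id=b.block_id,
                    lg_id=b.lg_id,
                    interval_cM=(lo.cm, hi.cm),
                    left_flank=lo.locus_id,
                    right_flank=hi.locus_id,
                    bp=t.bp,
                    status="interval",
                )
            )
    return placements, unplaced


def reconcile_across_species(
    placements: Iterable[Placement],
) -> list[ConsolidatedPlacement]:
    """Consolidate placements of each transcript across comparison species.

    If every placement of a transcript names the same linkage group, the
    consolidated interval is the intersection of the per-placement cM
    intervals when non-empty, else their union flagged
    ``inconsistent-interval``. Placements on different linkage groups are a
    ``conflict`` and yield no consolidated interval.
    """
    by_query: dict[str, list[Placement]] = {}
    for p in placements:
        by_query.setdefault(p.query_id, []).append(p)

    out: list[ConsolidatedPlacement] = []
    for query_id in sorted(by_query):
        group = by_query[query_id]
        lgs = {p.lg_id for p in group}
        if len(lgs) > 1:
            out.append(
                ConsolidatedPlacement(query_id, "conflict", None, None, len(group))
            )
            continue
        lg = group[0].lg_id
        left = max(p.interval_cM[0] for p in group)
        right = min(p.interval_cM[1] for p in group)
        if left <= right:
            out.append(
                ConsolidatedPlacement(
                    query_id, "consistent", lg, (left, right), len(group)
                )
            )
        else:
            union = (
                min(p.interval_cM[0] for p in group),
                max(p.interval_cM[1] for p in group),
            )
            out.append(
                ConsolidatedPlacement(
                    query_id, "inconsistent-interval", lg, union, len(group)
                )
            )
    return out


def placement_rate(
    placements: Iterable[Placement], transcript_ids: Iterable[str]
) -> PlacementSummary:
    """Fraction of transcripts with at least one placement, as a percent."""
    ids = set(transcript_ids)
    if not ids:
        raise ValidationError("placement_rate: no transcripts supplied")
    placed = {p.query_id for p in placements} & ids
    return PlacementSummary(
        n_transcripts=len(ids),
        n_placed=len(placed),
        percent_placed=round(100.0 * len(placed) / len(ids), 1),
    )


# ---------------------------------------------------------------------------
# TSV exports

def write_placements(placements: Sequence[Placement], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "query_id\tspecies\tlg\tcm_left\tcm_right\tleft_flank\t"
            "right_flank\tblock_id\tstatus\n"
        )
        for p in sorted(
            placements, key=lambda p: (p.query_id, p.species, p.block_id)
        ):
            fh.write(
                f"{p.query_id}\t{p.species}\t{p.lg_id}\t"
                f"{p.interval_cM[0]:.6f}\t{p.interval_cM[1]:.6f}\t"
                f"{p.left_flank}\t{p.right_flank}\t{p.block_id}\t{p.status}\n"
            )


def write_consolidated(records: Sequence[ConsolidatedPlacement], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tflag\tlg\tcm_left\tcm_right\tn_supporting\n")
        for r in sorted(records, key=lambda r: r.query_id):
            left = f"{r.interval_cM[0]:.6f}" if r.interval_cM else ""
            right = f"{r.interval_cM[1]:.6f}" if r.interval_cM else ""
            fh.write(
                f"{r.query_id}\t{r.flag}\t{r.lg_id or ''}\t{left}\t{right}\t"
                f"{r.n_supporting}\n"
            )


def write_unplaced(records: Sequence[Unplaced], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tspecies\treason\n")
        for r in sorted(records, key=lambda r: (r.query_id, r.species)):
            fh.write(f"{r.query_id}\t{r.species}\t{r.reason}\n")
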