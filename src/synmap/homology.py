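"""Tabular homology-hit parsing and anchor resolution.

Homology searches of marker (and transcript) sequences against each
comparison genome are consumed in the standard 12-column tabular dialect
(query, subject, %identity, alignment length, mismatches, gap opens,
qstart, qend, sstart, send, e-value, bitscore).

A *anchor* is a query resolved to a unique (chromosome, bp) position in one
comparison genome. Resolution applies two rules:

1. significance — only hits with e-value strictly below the threshold
   (default 1e-10) count;
2. uniqueness — a query with significant hits on two or more chromosomes of
   one comparison genome is discarded outright (multi-copy ambiguity).

For a query whose significant hits all fall on one chromosome, the best hit
(highest bitscore; ties broken by lower e-value, then chromosome id, then
lower coordinate) defines the anchor, and the anchor position is the
*smaller* of the hit's two subject coordinates so minus-strand hits get a
well-defined start. Strand itself is not used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import FormatError, ValidationError
from .map_io import ChromosomeSet, LinkageMap

#: e-value threshold below which a hit counts as significant.
DEFAULT_EVALUE = 1e-10

TABULAR_NCOLS = 12


@dataclass(frozen=True)
class HomologyHit:
    """One row of 12-column tabular search output (subject side only).

    ``s_start``/``s_end`` are kept exactly as printed: for minus-strand hits
    ``s_start`` exceeds ``s_end``.
    """

    query_id: str
    species: str
    chromosome: str
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if min(self.s_start, self.s_end) < 1:
            raise ValidationError(
                f"hit {self.query_id!r}: subject coordinates must be >= 1"
            )
        if self.evalue < 0:
            raise ValidationError(
                f"hit {self.query_id!r}: negative e-value {self.evalue!r}"
            )

    @property
    def subject_start(self) -> int:
        """1-based anchor coordinate: min of the two subject coordinates."""
        return min(self.s_start, self.s_end)


@dataclass(frozen=True)
class Anchor:
    """A query resolved to a unique single-chromosome position.

    For mapped loci, ``lg_id``/``cm`` carry the map position; for unmapped
    queries (candidate-gene transcripts) both are ``None``.
    """

    locus_id: str
    species: str
    chromosome: str
    bp: int
    lg_id: Optional[str] = None
    cm: Optional[float] = None

    @property
    def is_mapped(self) -> bool:
        return self.lg_id is not None


@dataclass(frozen=True)
class Discard:
    """A query removed during anchor resolution, with the reason."""

    query_id: str
    species: str
    reason: str


def read_tabular_hits(path, species: str) -> list[HomologyHit]:
    """Parse a 12-column tabular hit file; empty files yield an empty list."""
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != TABULAR_NCOLS:
                raise FormatError(
                    f"{path}:{lineno}: expected {TABULAR_NCOLS} tab-separated "
                    f"columns, found {len(fields)}"
                )
            try:
                hits.append(
                    HomologyHit(
                        query_id=fields[0],
                        species=species,
                        chromosome=fields[1],
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_tabular_hits(hits: Sequence[HomologyHit], path) -> None:
    """Emit hits in the 12-column dialect (query-side fields synthesised).

    Only the subject-side fields round-trip; query coordinates and identity
    statistics are written as placeholders consistent with the alignment
    length implied by the subject span.
    """
    with open(path, "w") as fh:
        for h in hits:
            alen = abs(h.s_end - h.s_start) + 1
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.chromosome,
                        "100.00",
                        str(alen),
                        "0",
                        "0",
                        "1",
                        str(alen),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


def filter_significant(
    hits: Iterable[HomologyHit], threshold: float = DEFAULT_EVALUE
) -> list[HomologyHit]:
    """Keep hits with e-value strictly below ``threshold``."""
    if not threshold > 0:
        raise ValidationError(f"e-value threshold must be > 0, got {threshold!r}")
    return [h for h in hits if h.evalue < threshold]


def _best_hit(hits: Sequence[HomologyHit]) -> HomologyHit:
    # highest bitscore; ties: lower e-value, then chromosome, then lower bp
    return min(
        hits,
        key=lambda h: (-h.bitscore, h.evalue, h.chromosome, h.subject_start),
    )


def resolve_anchors(
    hits: Iterable[HomologyHit],
    linkage_map: Optional[LinkageMap] = None,
    sizes: Optional[ChromosomeSet] = None,
) -> tuple[list[Anchor], list[Discard]]:
    """Resolve significance-filtered hits to unique per-query anchors.

    Returns ``(anchors, discards)``; every distinct (query, species) ends up
    in exactly one of the two lists. Queries present in ``linkage_map``
    become mapped anchors carrying their linkage group and cM position;
    unknown queries pass through as unmapped anchors for transcript
    placement. Results are deterministic and independent of hit order.
    """
    locus_index = linkage_map.locus_index() if linkage_map is not None else {}
    by_query: dict[tuple[str, str], list[HomologyHit]] = {}
    for h in hits:
        by_query.setdefault((h.query_id, h.species), []).append(h)

    anchors: list[Anchor] = []
    discards: list[Discard] = []
    for (query_id, species) in sorted(by_query):
        qhits = by_query[(query_id, species)]
        chroms = {h.chromosome for h in qhits}
        if len(chroms) > 1:
            discards.append(Discard(query_id, species, "multi-chromosome"))
            continue
        best = _best_hit(qhits)
        bp = best.subject_start
        if sizes is not None:
            if best.chromosome not in sizes:
                raise ValidationError(
                    f"{species}: hit for {query_id!r} names unknown "
                    f"chromosome {best.chromosome!r}"
                )
            if max(best.s_start, best.s_end) > sizes[best.chromosome]:
                raise ValidationError(
                    f"{species}: anchor for {query_id!r} at "
                    f"{best.chromosome}:{bp} exceeds chromosome length "
                    f"{sizes[best.chromosome]}"
                )
        locus = locus_index.get(query_id)
        anchors.append(
            Anchor(
                locus_id=query_id,
                species=species,
                chromosome=best.chromosome,
                bp=bp,
                lg_id=locus.linkage_group if locus else None,
                cm=locus.position if locus else None,
            )
        )
    return anchors, discards


# ---------------------------------------------------------------------------
# Anchor table I/O (TSV) so CLI stages can hand results to each other.

ANCHOR_COLUMNS = ("locus_id", "lg", "cm", "species", "chromosome", "bp")


def write_anchors(anchors: Sequence[Anchor], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ANCHOR_COLUMNS) + "\n")
        for a in sorted(
            anchors, key=lambda a: (a.species, a.lg_id or "", a.cm or 0.0, a.locus_id)
        ):
            fh.write(
                "\t".join(
                    [
                        a.locus_id,
                        a.lg_id or "",
                        f"{a.cm:.6f}" if a.cm is not None else "",
                        a.species,
                        a.chromosome,
                        str(a.bp),
                    ]
                )
                + "\n"
            )


def read_anchors(path) -> list[Anchor]:
    anchors: list[Anchor] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ANCHOR_COLUMNS:
            raise FormatError(
                f"{path}: expected header {ANCHOR_COLUMNS}, found {tuple(header)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(ANCHOR_COLUMNS):
                raise FormatError(f"{path}:{lineno}: wrong field count")
            locus_id, lg, cm, species, chrom, bp = fields
            anchors.append(
                Anchor(
                    locus_id=locus_id,
                    species=species,
                    chromosome=chrom,
                    bp=int(bp),
                    lg_id=lg or None,
                    cm=float(cm) if cm else None,
                )
            )
    return anchors


def write_discards(discards: Sequence[Discard], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tspecies\treason\n")
        for d in sorted(discards, key=lambda d: (d.species, d.query_id)):
            fh.write(f"{d.query_id}\t{d.species}\t{d.reason}\n")
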