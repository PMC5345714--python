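"""Linkage-map data model, I/O and summary statistics.

A linkage map is a set of linkage groups (LGs), each an ordered list of
mapped loci with positions in centiMorgans (cM). Maps are exchanged as a
tab-separated table with header ``locus_id  lg  cm  class  sequence``;
chromosome sizes of comparison genomes use the two-column ``chrom.sizes``
dialect (no header).

Summary statistics follow the usual linkage-map conventions:

* total map length = sum of per-group lengths (a group's length is the
  maximum cM position; maps start at 0),
* mean marker interval = total length / (n_loci - n_groups), i.e. the mean
  gap between adjacent loci *within* groups only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pandas as pd

from .errors import FormatError, ValidationError

#: Closed set of marker classes: RAD contigs, anonymous microsatellites,
#: and microsatellites linked to expressed sequence tags.
MARKER_CLASSES = ("RAD", "SSR", "EST-SSR")

MAP_COLUMNS = ("locus_id", "lg", "cm", "class", "sequence")


@dataclass(frozen=True)
class MapLocus:
    """A single mapped marker.

    Parameters
    ----------
    locus_id : unique marker identifier.
    linkage_group : identifier of the group the marker maps to.
    position : map position in cM; must be >= 0.
    marker_class : one of :data:`MARKER_CLASSES`.
    sequence : optional nucleotide sequence of the marker (used upstream
        for homology searches; not interpreted here).
    """

    locus_id: str
    linkage_group: str
    position: float
    marker_class: str = "RAD"
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise ValidationError("locus with empty locus_id")
        if not (self.position >= 0):  # also rejects NaN
            raise ValidationError(
                f"locus {self.locus_id!r}: negative or undefined cM position "
                f"{self.position!r}"
            )
        if self.marker_class not in MARKER_CLASSES:
            raise ValidationError(
                f"locus {self.locus_id!r}: unknown marker class "
                f"{self.marker_class!r} (expected one of {MARKER_CLASSES})"
            )


@dataclass
class LinkageGroup:
    """An ordered linkage group.

    Loci are kept sorted by non-decreasing cM position; ties (zero-
    recombination bins) are allowed and their relative order is preserved
    as given (stable sort).
    """

    lg_id: str
    loci: list[MapLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.loci = sorted(self.loci, key=lambda l: l.position)

    @property
    def length(self) -> float:
        """Group length in cM: the maximum position (0 for <2 loci)."""
        if len(self.loci) < 2:
            return 0.0
        return max(l.position for l in self.loci)

    @property
    def n_loci(self) -> int:
        return len(self.loci)


@dataclass
class LinkageMap:
    """A full linkage map: a collection of linkage groups."""

    groups: dict[str, LinkageGroup] = field(default_factory=dict)
    species_label: str = "mapped_species"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for lg in self.groups.values():
            for locus in lg.loci:
                if locus.locus_id in seen:
                    raise ValidationError(
                        f"duplicate locus_id {locus.locus_id!r} in map"
                    )
                seen.add(locus.locus_id)

    @property
    def n_loci(self) -> int:
        return sum(g.n_loci for g in self.groups.values())

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def total_length(self) -> float:
        # summed in sorted group order so the float result does not depend
        # on dict insertion order
        return sum(self.groups[k].length for k in sorted(self.groups))

    def iter_loci(self) -> Iterator[MapLocus]:
        for lg_id in self.groups:
            yield from self.groups[lg_id].loci

    def locus_index(self) -> dict[str, MapLocus]:
        """Mapping locus_id -> MapLocus over the whole map."""
        return {l.locus_id: l for l in self.iter_loci()}

    def to_frame(self) -> pd.DataFrame:
        """Canonical tabular form: groups by lg_id, loci by (cm, locus_id)."""
        rows = []
        for lg_id in sorted(self.groups):
            for l in sorted(
                self.groups[lg_id].loci, key=lambda x: (x.position, x.locus_id)
            ):
                rows.append(
                    {
                        "locus_id": l.locus_id,
                        "lg": lg_id,
                        "cm": l.position,
                        "class": l.marker_class,
                        "sequence": l.sequence if l.sequence else "",
                    }
                )
        return pd.DataFrame(rows, columns=list(MAP_COLUMNS))


@dataclass(frozen=True)
class ChromosomeSet:
    """Chromosome lengths (bp) of one comparison genome."""

    species: str
    sizes: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.sizes.items():
            if int(length) != length or length <= 0:
                raise ValidationError(
                    f"{self.species}: chromosome {chrom!r} has non-positive "
                    f"or non-integer length {length!r}"
                )

    @property
    def total_bp(self) -> int:
        return int(sum(self.sizes.values()))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __getitem__(self, chrom: str) -> int:
        return int(self.sizes[chrom])


@dataclass(frozen=True)
class MapStats:
    """Whole-map summary statistics (Table-1 style)."""

    n_loci: int
    n_groups: int
    total_length_cM: float
    mean_lg_size_cM: float
    mean_loci_per_group: float
    #: None when every group has a single locus (no within-group intervals).
    mean_marker_interval_cM: Optional[float]


def build_map(
    loci: Iterable[MapLocus], species_label: str = "mapped_species"
) -> LinkageMap:
    """Assemble a LinkageMap from a flat iterable of loci."""
    groups: dict[str, list[MapLocus]] = {}
    for locus in loci:
        groups.setdefault(locus.linkage_group, []).append(locus)
    return LinkageMap(
        groups={
            lg_id: LinkageGroup(lg_id=lg_id, loci=members)
            for lg_id, members in groups.items()
        },
        species_label=species_label,
    )


def read_linkage_map(path, species_label: str = "mapped_species") -> LinkageMap:
    """Read a linkage map from its TSV exchange format.

    The file must carry a header with columns ``locus_id``, ``lg``, ``cm``,
    ``class`` and ``sequence`` (sequence may be empty). Loci are sorted by
    position within each group; cM ties keep file order.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"locus_id": str, "lg": str}, keep_default_na=False
    )
    for col in MAP_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    loci = []
    for locus_id, lg, cm_raw, mclass, seq in zip(
        df["locus_id"], df["lg"], df["cm"], df["class"], df["sequence"]
    ):
        try:
            cm = float(cm_raw)
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"{path}: non-numeric cM value {cm_raw!r} for locus {locus_id!r}"
            ) from exc
        seq = str(seq or "")
        loci.append(
            MapLocus(
                locus_id=str(locus_id),
                linkage_group=str(lg),
                position=cm,
                marker_class=str(mclass),
                sequence=seq or None,
            )
        )
    return build_map(loci, species_label=species_label)


def write_linkage_map(linkage_map: LinkageMap, path) -> None:
    """Write a map in the TSV exchange format (deterministic ordering)."""
    df = linkage_map.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_chrom_sizes(path, species: str) -> ChromosomeSet:
    """Read a two-column ``<chrom>\\t<length>`` table (UCSC chrom.sizes)."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["chrom", "length"], dtype=str
    )
    sizes: dict[str, int] = {}
    for row in df.itertuples(index=False):
        try:
            length = int(row.length)
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path}: non-integer length {row.length!r} for chromosome "
                f"{row.chrom!r}"
            ) from exc
        if row.chrom in sizes:
            raise ValidationError(f"{path}: duplicate chromosome {row.chrom!r}")
        sizes[str(row.chrom)] = length
    return ChromosomeSet(species=species, sizes=sizes)


def write_chrom_sizes(chromset: ChromosomeSet, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(chromset.sizes):
            fh.write(f"{chrom}\t{chromset.sizes[chrom]}\n")


def map_statistics(linkage_map: LinkageMap) -> MapStats:
    """Compute whole-map summary statistics.

    Mean marker interval is total map length divided by the number of
    within-group adjacencies, ``n_loci - n_groups``; it is undefined
    (``None``) when each group holds a single locus.
    """
    n_loci = linkage_map.n_loci
    n_groups = linkage_map.n_groups
    if n_loci == 0 or n_groups == 0:
        raise ValidationError("cannot summarise an empty map")
    total = linkage_map.total_length
    interval = total / (n_loci - n_groups) if n_loci > n_groups else None
    return MapStats(
        n_loci=n_loci,
        n_groups=n_groups,
        total_length_cM=total,
        mean_lg_size_cM=total / n_groups,
        mean_loci_per_group=n_loci / n_groups,
        mean_marker_interval_cM=interval,
    )


def maps_equal(a: LinkageMap, b: LinkageMap, tol: float = 1e-9) -> bool:
    """Field-by-field equality of two maps up to cM rounding.

    Loci are compared in canonical order (group, position, locus_id), so two
    maps that differ only in the stored order of zero-recombination ties
    compare equal.
    """
    fa, fb = a.to_frame(), b.to_frame()
    if len(fa) != len(fb) or list(fa.columns) != list(fb.columns):
        return False
    for col in ("locus_id", "lg", "class", "sequence"):
        if not (fa[col].values == fb[col].values).all():
            return False
    return all(
        math.isclose(x, y, abs_tol=tol) for x, y in zip(fa["cm"], fb["cm"])
    )
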