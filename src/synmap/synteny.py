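"""Shared-synteny block detection.

A syntenic block is a maximal run of >=2 mapped anchors from one linkage
group that (a) all hit the same chromosome of the comparison genome —
an intervening anchor on a different chromosome terminates a run — and
(b) are collinear: their bp positions follow their cM order in one
direction (the block orientation), up to tolerated small departures.

Tolerance rule
--------------
Anchors in a candidate run are taken in cM order (ties by bp, then
locus_id). Under an orientation ``s`` (+1 ascending, -1 descending), a pair
of anchors with distinct cM positions is *discordant* when their bp order
contradicts ``s``. A discordant pair is tolerated only when the two anchors
are close together on *both* axes:

    |dcm| < tau * (linkage-group length)   and   |dbp| < tau * (chromosome length)

with tau = 0.025 by default. The check runs over every pair in the run, not
only adjacent ones: a reversed segment whose span exceeds tolerance always
produces an intolerable discordant pair (its two ends), however small the
marker gaps inside it, while genuinely local order noise (assembly or map
error) is forgiven. Anchors tied in cM never form discordant pairs — any
genome order within a zero-recombination bin is consistent with the map.

Segmentation
------------
For each (species, linkage group), the cM-sorted anchor sequence is
partitioned into contiguous feasible runs by exact dynamic programming,
minimising the number of runs, then maximising the number of anchors in
runs of length >= 2, then preferring leftmost-longest runs. Runs of length
1 are not blocks (a block needs at least two loci) but are reported as
unblocked anchors by :func:`blocks_overlap_check`. A small brute-force
verifier, :func:`oracle_segment`, enumerates every segmentation of a short
anchor sequence and serves as an independent correctness oracle in tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as _sstats

from .errors import ValidationError
from .homology import Anchor
from .map_io import ChromosomeSet, LinkageMap

DEFAULT_TAU = 0.025


@dataclass(frozen=True)
class ToleranceRule:
    """Collinearity tolerance as a fraction of each axis length."""

    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        if not (0 <= self.tau < 1):
            raise ValidationError(f"tau must be in [0, 1), got {self.tau!r}")


@dataclass(frozen=True)
class SyntenyBlock:
    """A detected region of shared synteny."""

    block_id: str
    species: str
    lg_id: str
    chromosome: str
    anchors: tuple[Anchor, ...]
    orientation: int  # +1, -1, or 0 when undefined (all cM or all bp tied)
    map_span_cM: tuple[float, float]
    genome_span_bp: tuple[int, int]

    @property
    def n_loci(self) -> int:
        return len(self.anchors)

    @property
    def map_size_cM(self) -> float:
        return self.map_span_cM[1] - self.map_span_cM[0]

    @property
    def genome_size_bp(self) -> int:
        return self.genome_span_bp[1] - self.genome_span_bp[0]

    def contains_bp(self, bp: int) -> bool:
        return self.genome_span_bp[0] <= bp <= self.genome_span_bp[1]


@dataclass
class OverlapReport:
    """Disjointness / coverage report over a set of detected blocks."""

    disjoint: bool
    duplicated_loci: tuple[str, ...]
    coverage_by_species: dict[str, float] = field(default_factory=dict)
    unblocked_by_species: dict[str, int] = field(default_factory=dict)


def _sort_key(a: Anchor):
    return (a.cm, a.bp, a.locus_id)


def _feasible_orientations(
    cm: np.ndarray, bp: np.ndarray, cm_thr: float, bp_thr: float
) -> tuple[bool, bool]:
    """Whether a (single-chromosome) run is collinear under +1 / -1.

    Vectorised all-pairs check. ``cm`` is non-decreasing (the run is in map
    order); bp ties and cm ties are concordant under either orientation.
    """
    n = len(cm)
    if n < 2:
        return True, True
    iu, ju = np.triu_indices(n, k=1)
    dcm = cm[ju] - cm[iu]  # >= 0
    dbp = bp[ju] - bp[iu]
    tied = dcm == 0
    tol = (dcm < cm_thr) & (np.abs(dbp) < bp_thr)
    up_bad = (~tied) & (dbp < 0) & ~tol
    down_bad = (~tied) & (dbp > 0) & ~tol
    return not up_bad.any(), not down_bad.any()


def run_is_feasible(
    cm: Sequence[float],
    bp: Sequence[int],
    chrom: Sequence[str],
    cm_thr: float,
    bp_thr: float,
) -> bool:
    """Feasibility of one candidate run (single chromosome + collinearity)."""
    if len(set(chrom)) > 1:
        return False
    up, down = _feasible_orientations(
        np.asarray(cm, dtype=float), np.asarray(bp, dtype=float), cm_thr, bp_thr
    )
    return up or down


def _max_reach(
    cm: np.ndarray,
    bp: np.ndarray,
    chrom: Sequence[str],
    cm_thr: float,
    bp_thr: np.ndarray,
) -> np.ndarray:
    """reach[i] = largest j such that the run [i..j] is feasible.

    Feasibility is hereditary on contiguous subruns, so each start has a
    single maximal reach. Extension from each start is incremental: adding
    anchor j keeps an orientation alive iff every pair (k, j), i<=k<j, is
    concordant or tolerated under it.
    """
    n = len(cm)
    reach = np.empty(n, dtype=int)
    for i in range(n):
        up = down = True
        j = i
        while j + 1 < n:
            nxt = j + 1
            if chrom[nxt] != chrom[i]:
                break
            dcm = cm[nxt] - cm[i : nxt]
            dbp = bp[nxt] - bp[i : nxt]
            tied = dcm == 0
            tol = (dcm < cm_thr) & (np.abs(dbp) < bp_thr[i])
            if up and ((~tied) & (dbp < 0) & ~tol).any():
                up = False
            if down and ((~tied) & (dbp > 0) & ~tol).any():
                down = False
            if not (up or down):
                break
            j = nxt
        reach[i] = j
    return reach


def _segment(reach: np.ndarray) -> list[tuple[int, int]]:
    """Optimal segmentation given per-start maximal reach.

    Minimises the number of runs, then the number of singleton runs (i.e.
    maximises anchors inside runs of length >= 2), then prefers the
    leftmost-longest runs. Returns [start, end] index pairs (inclusive).
    """
    n = len(reach)
    INF = (n + 1, n + 1)
    # opt[i] = (min runs, min singleton-anchors) for suffix starting at i
    opt: list[tuple[int, int]] = [INF] * (n + 1)
    opt[n] = (0, 0)
    for i in range(n - 1, -1, -1):
        best = INF
        for j in range(i, reach[i] + 1):
            runs, singles = opt[j + 1]
            cand = (runs + 1, singles + (1 if j == i else 0))
            if cand < best:
                best = cand
        opt[i] = best
    # forward reconstruction: longest first run achieving the optimum
    runs_out: list[tuple[int, int]] = []
    i = 0
    while i < n:
        target = opt[i]
        chosen = i
        for j in range(i, reach[i] + 1):
            runs, singles = opt[j + 1]
            if (runs + 1, singles + (1 if j == i else 0)) == target:
                chosen = j
        runs_out.append((i, chosen))
        i = chosen + 1
    return runs_out


def _orientation(cm: np.ndarray, bp: np.ndarray) -> int:
    """Block orientation: sign of the cM~bp rank correlation (0 if undefined)."""
    if len(cm) < 2 or len(set(cm.tolist())) < 2 or len(set(bp.tolist())) < 2:
        return 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = _sstats.spearmanr(cm, bp).statistic
    if np.isnan(rho) or rho == 0:
        return 0
    return 1 if rho > 0 else -1


def detect_blocks(
    anchors: Iterable[Anchor],
    linkage_map: LinkageMap,
    sizes_by_species: dict[str, ChromosomeSet],
    rule: ToleranceRule = ToleranceRule(),
) -> list[SyntenyBlock]:
    """Detect shared-synteny blocks from resolved mapped anchors.

    Anchors must be mapped (carry lg_id/cm) and unique per (locus, species).
    Returns blocks sorted by (species, lg, map start); every anchor belongs
    to at most one block, and runs of a single anchor are dropped.
    """
    anchors = [a for a in anchors]
    for a in anchors:
        if not a.is_mapped:
            raise ValidationError(
                f"unmapped anchor {a.locus_id!r} passed to detect_blocks"
            )
        if a.lg_id not in linkage_map.groups:
            raise ValidationError(
                f"anchor {a.locus_id!r} references unknown linkage group "
                f"{a.lg_id!r}"
            )
        sizes = sizes_by_species.get(a.species)
        if sizes is None or a.chromosome not in sizes:
            raise ValidationError(
                f"anchor {a.locus_id!r} ({a.species}) references unknown "
                f"chromosome {a.chromosome!r}"
            )

    blocks: list[SyntenyBlock] = []
    keyfunc = lambda a: (a.species, a.lg_id)
    for (species, lg_id), group in groupby(sorted(anchors, key=lambda a: (
            a.species, a.lg_id, *_sort_key(a))), key=keyfunc):
        members = list(group)
        cm = np.array([a.cm for a in members], dtype=float)
        bp = np.array([a.bp for a in members], dtype=float)
        chrom = [a.chromosome for a in members]
        lg_len = linkage_map.groups[lg_id].length
        cm_thr = rule.tau * lg_len
        sizes = sizes_by_species[species]
        bp_thr = np.array([rule.tau * sizes[c] for c in chrom])
        reach = _max_reach(cm, bp, chrom, cm_thr, bp_thr)
        k = 0
        for start, end in _segment(reach):
            if end - start + 1 < 2:
                continue
            sub = tuple(members[start : end + 1])
            k += 1
            blocks.append(
                SyntenyBlock(
                    block_id=f"{species}:{lg_id}:{k:03d}",
                    species=species,
                    lg_id=lg_id,
                    chromosome=chrom[start],
                    anchors=sub,
                    orientation=_orientation(cm[start : end + 1], bp[start : end + 1]),
                    map_span_cM=(float(cm[start : end + 1].min()),
                                 float(cm[start : end + 1].max())),
                    genome_span_bp=(int(bp[start : end + 1].min()),
                                    int(bp[start : end + 1].max())),
                )
            )
    blocks.sort(key=lambda b: (b.species, b.lg_id, b.map_span_cM, b.block_id))
    return blocks


def oracle_segment(
    anchors: Sequence[Anchor],
    rule: ToleranceRule,
    lg_length: float,
    chrom_length: int,
) -> list[tuple[int, int]]:
    """Brute-force segmentation oracle for short single-LG anchor lists.

    Enumerates every segmentation of the cM-sorted sequence into contiguous
    runs, accepts a segmentation iff each run is collinear under some
    orientation with all discordant pairs tolerated, and returns the one
    minimising (number of runs, anchors outside runs of length >= 2,
    then lexicographically preferring longer early runs). Refuses more than
    12 anchors. Independent of :func:`detect_blocks` internals: feasibility
    is re-derived with explicit pair loops.
    """
    n = len(anchors)
    if n > 12:
        raise ValidationError("oracle_segment refuses more than 12 anchors")
    if n == 0:
        return []
    ordered = sorted(anchors, key=_sort_key)
    cm = [a.cm for a in ordered]
    bp = [a.bp for a in ordered]
    chrom = [a.chromosome for a in ordered]
    cm_thr = rule.tau * lg_length
    bp_thr = rule.tau * chrom_length

    def run_ok(i: int, j: int) -> bool:  # inclusive interval
        if len({chrom[k] for k in range(i, j + 1)}) > 1:
            return False
        for s in (1, -1):
            ok = True
            for a in range(i, j + 1):
                for b in range(a + 1, j + 1):
                    if cm[a] == cm[b] or bp[a] == bp[b]:
                        continue
                    concordant = (bp[b] - bp[a]) * s > 0
                    if concordant:
                        continue
                    if abs(cm[b] - cm[a]) < cm_thr and abs(bp[b] - bp[a]) < bp_thr:
                        continue
                    ok = False
                    break
                if not ok:
                    break
            if ok:
                return True
        return False

    feasible = {}
    for i in range(n):
        for j in range(i, n):
            feasible[(i, j)] = run_ok(i, j)

    best_key = None
    best_runs: Optional[list[tuple[int, int]]] = None
    # bitmask over the n-1 gaps: set bit -> cut after that position
    for mask in range(1 << (n - 1)):
        runs = []
        start = 0
        for g in range(n - 1):
            if mask >> g & 1:
                runs.append((start, g))
                start = g + 1
        runs.append((start, n - 1))
        if not all(feasible[r] for r in runs):
            continue
        singles = sum(1 for (i, j) in runs if i == j)
        lex = tuple(-(j - i + 1) for i, j in runs)
        key = (len(runs), singles, lex)
        if best_key is None or key < best_key:
            best_key = key
            best_runs = runs
    assert best_runs is not None  # singleton segmentation is always feasible
    return best_runs


def blocks_overlap_check(
    blocks: Sequence[SyntenyBlock], anchors: Optional[Sequence[Anchor]] = None
) -> OverlapReport:
    """Verify block disjointness and report per-species anchor coverage."""
    seen: dict[tuple[str, str], int] = {}
    for b in blocks:
        for a in b.anchors:
            seen[(a.species, a.locus_id)] = seen.get((a.species, a.locus_id), 0) + 1
    dupes = tuple(sorted(loc for (_, loc), c in seen.items() if c > 1))
    report = OverlapReport(disjoint=not dupes, duplicated_loci=dupes)
    if anchors is not None:
        per_species_total: dict[str, int] = {}
        for a in anchors:
            per_species_total[a.species] = per_species_total.get(a.species, 0) + 1
        blocked: dict[str, int] = {}
        for (sp, _), c in seen.items():
            blocked[sp] = blocked.get(sp, 0) + (1 if c else 0)
        for sp, total in sorted(per_species_total.items()):
            nb = blocked.get(sp, 0)
            report.coverage_by_species[sp] = nb / total if total else 0.0
            report.unblocked_by_species[sp] = total - nb
    return report
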