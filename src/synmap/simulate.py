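"""Synthetic data generator with known synteny ground truth.

The generator builds an *ancestral* coordinate system shared by the mapped
species and each comparison genome: for every linkage group, marker
positions in bp are drawn on one ancestral chromosome and the cM scale is a
monotone, piecewise-linear transform of bp (piecewise-constant
recombination rate), with a configurable fraction of loci collapsed into
zero-recombination bins (tied cM). Each comparison genome is then derived
by applying planted rearrangements to contiguous anchor runs —

* inversions: the bp order of a run is reversed in place (mirrored within
  its span),
* translocations: a run is moved to a uniformly chosen other chromosome,

followed by truncated-Gaussian bp jitter emulating assembly error. Homology
hits are emitted in the 12-column tabular dialect, with configurable decoy
rates (loci with no significant hit, multi-chromosome hits, weak e-values,
secondary same-chromosome hits) so all filter paths are exercised.
Candidate transcripts are planted at known positions: between two adjacent
anchors of a truth block (placeable), inside two-anchor blocks (too small
to place), in anchor-free chromosome tails (outside all blocks), or as
multi-chromosome / sub-threshold decoys.

Ground truth
------------
Truth blocks are the runs a collinearity detector with the configured
tolerance should report. They follow the planted rearrangement boundaries
with one deliberate convention: rearrangement breakpoints are genuinely
ambiguous at the margin, so the leading anchors of an inverted run whose
mirrored positions still continue the preceding collinear run within
tolerance are credited to the preceding block, and a trailing remainder
whose span is below tolerance on both axes is credited to the following
block. Transcripts are never planted across these ambiguous margins, so
transcript truth is exact. All randomness derives from the single seed.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .homology import Anchor, HomologyHit, write_tabular_hits
from .map_io import (
    ChromosomeSet,
    LinkageMap,
    MapLocus,
    build_map,
    write_chrom_sizes,
    write_linkage_map,
)
from .placement import Placement
from .synteny import SyntenyBlock

_MARKER_CLASS_PROBS = {"RAD": 0.79, "SSR": 0.19, "EST-SSR": 0.02}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated comparative-mapping study.

    Defaults emulate the scale of a dense fish linkage map compared against
    chromosome-level assemblies: 24 linkage groups of ~95 loci and ~88 cM,
    24 Mb chromosomes, about a third of loci in zero-recombination bins,
    and two comparison genomes carrying inversions and translocations of a
    few anchors each.
    """

    n_lgs: int = 24
    loci_per_lg: int = 95
    lg_length_cM: float = 87.72
    chrom_length_bp: int = 24_000_000
    n_species: int = 2
    n_inversions: int = 48
    inversion_size_range: tuple[int, int] = (3, 6)
    n_translocations: int = 12
    translocation_size_range: tuple[int, int] = (2, 4)
    jitter_sd_bp: float = 10_000.0
    jitter_max_bp: float = 30_000.0
    tie_fraction: float = 0.30
    n_transcripts: int = 724
    evalue_range: tuple[float, float] = (1e-50, 1e-12)
    no_hit_rate: float = 0.35
    multi_chrom_rate: float = 0.03
    weak_hit_rate: float = 0.03
    extra_hit_rate: float = 0.10
    #: tolerance convention the truth blocks are defined against
    tau: float = 0.025
    #: planted rearrangements must span at least this fraction of one axis
    min_rearrangement_span_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_lgs, self.loci_per_lg) < 1:
            raise ValidationError("n_lgs and loci_per_lg must be >= 1")
        for name in ("n_inversions", "n_translocations", "n_transcripts"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in (
            "tie_fraction",
            "no_hit_rate",
            "multi_chrom_rate",
            "weak_hit_rate",
            "extra_hit_rate",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.inversion_size_range[0] < 2 or self.translocation_size_range[0] < 2:
            raise ValidationError("rearranged runs need at least 2 anchors")
        if not (0 <= self.tau < 1):
            raise ValidationError("tau must be in [0, 1)")
        if self.jitter_max_bp < 0 or self.jitter_sd_bp < 0:
            raise ValidationError("jitter parameters must be >= 0")


@dataclass(frozen=True)
class TruthBlock:
    species: str
    lg_id: str
    chromosome: str
    locus_ids: tuple[str, ...]
    orientation: int


@dataclass(frozen=True)
class TranscriptTruth:
    query_id: str
    category: str  # in_block | small_block | outside | multi_chrom | weak
    lg_id: Optional[str] = None
    cm: Optional[float] = None
    block_n_loci: Optional[int] = None


@dataclass
class SimTruth:
    blocks: list[TruthBlock] = field(default_factory=list)
    transcripts: dict[str, TranscriptTruth] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "blocks": [asdict(b) for b in self.blocks],
                "transcripts": {q: asdict(t) for q, t in sorted(self.transcripts.items())},
            },
            indent=1,
            sort_keys=True,
        )


@dataclass(frozen=True)
class RecoveryMetrics:
    block_precision: float
    block_recall: float
    placement_recall: float
    false_placement_rate: float
    n_truth_blocks: int
    n_detected_blocks: int


@dataclass
class SimResult:
    """Everything one simulation produced, plus its ground truth."""

    config: SimConfig
    linkage_map: LinkageMap
    chromosomes: dict[str, ChromosomeSet]
    locus_hits: dict[str, list[HomologyHit]]
    transcript_hits: dict[str, list[HomologyHit]]
    truth: SimTruth

    @property
    def species(self) -> list[str]:
        return sorted(self.chromosomes)

    def transcript_ids(self) -> list[str]:
        return sorted(self.truth.transcripts)

    def write(self, outdir) -> dict[str, str]:
        """Emit the exact formats the pipeline consumes; returns the paths."""
        os.makedirs(outdir, exist_ok=True)
        paths = {"map": os.path.join(outdir, "map.tsv")}
        write_linkage_map(self.linkage_map, paths["map"])
        for sp in self.species:
            p = os.path.join(outdir, f"{sp}.chrom.sizes")
            write_chrom_sizes(self.chromosomes[sp], p)
            paths[f"{sp}.chrom.sizes"] = p
            p = os.path.join(outdir, f"{sp}.hits.tsv")
            write_tabular_hits(self.locus_hits[sp], p)
            paths[f"{sp}.hits"] = p
            p = os.path.join(outdir, f"{sp}.transcript_hits.tsv")
            write_tabular_hits(self.transcript_hits[sp], p)
            paths[f"{sp}.transcript_hits"] = p
        paths["truth"] = os.path.join(outdir, "truth.json")
        with open(paths["truth"], "w") as fh:
            fh.write(self.truth.to_json() + "\n")
        return paths


# ---------------------------------------------------------------------------


def _draw_evalue(rng, lo: float, hi: float) -> float:
    return float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))


def _make_hit(rng, query, chrom, bp, evalue, bitscore, alen) -> HomologyHit:
    s1, s2 = bp, bp + alen - 1
    if rng.random() < 0.5:  # minus strand: coordinates printed reversed
        s1, s2 = s2, s1
    return HomologyHit(
        query_id=query,
        species="",  # filled by caller
        chromosome=chrom,
        s_start=s1,
        s_end=s2,
        evalue=evalue,
        bitscore=bitscore,
    )


@dataclass
class _Op:
    kind: str  # "inv" | "trans"
    lg: int
    start: int  # anchor-sequence index, inclusive
    end: int
    span_lo: float = 0.0  # ancestral bp span of the run
    span_hi: float = 0.0
    target_chrom: Optional[str] = None
    target_lo: float = 0.0


def _sample_ops(rng, cfg, anch_abp, anch_cm, lg_lengths, chrom_of_lg, chrom_len):
    """Plant non-overlapping rearrangement runs with clean margins."""
    by_lg: dict[int, list[_Op]] = {}
    plans = [("inv", cfg.n_inversions, cfg.inversion_size_range), (
        "trans", cfg.n_translocations, cfg.translocation_size_range)]
    frac = cfg.min_rearrangement_span_frac

    def candidates(kind: str, size_range: tuple[int, int]) -> list[tuple[int, int, int]]:
        out = []
        for lg in range(cfg.n_lgs):
            m = len(anch_abp[lg])
            cm = anch_cm[lg]
            abp = anch_abp[lg]
            for size in range(size_range[0], size_range[1] + 1):
                if m < size + 5:
                    continue
                for start in range(2, m - size - 1):
                    end = start + size - 1
                    # >=2 untouched anchors between runs and at both LG ends
                    if any(
                        not (start - o.end >= 3 or o.start - end >= 3)
                        for o in by_lg.get(lg, [])
                    ):
                        continue
                    # rearranged runs must sit in tie-free stretches: a
                    # breakpoint inside a zero-recombination bin is
                    # unresolvable on the map axis, so truth there would be
                    # ill-defined
                    if np.any(np.diff(cm[start - 1 : end + 2]) <= 0):
                        continue
                    if kind == "inv" and (
                        abp[end] - abp[start] < frac * chrom_len
                        and cm[end] - cm[start] < frac * lg_lengths[lg]
                    ):
                        continue  # below tolerance: would not split anything
                    out.append((lg, start, end))
        return out

    for kind, count, size_range in plans:
        for i in range(count):
            cand = candidates(kind, size_range)
            if not cand:
                raise ValidationError(
                    f"infeasible simulation config: no room to place "
                    f"{kind} {i + 1} of {count} (too many or too large "
                    "rearrangements for the anchor density)"
                )
            lg, start, end = cand[int(rng.integers(len(cand)))]
            abp = anch_abp[lg]
            op = _Op(kind, lg, start, end, span_lo=float(abp[start]),
                     span_hi=float(abp[end]))
            if kind == "trans":
                others = [c for i2, c in enumerate(chrom_of_lg) if i2 != lg]
                op.target_chrom = others[int(rng.integers(len(others)))]
                width = op.span_hi - op.span_lo
                hi = max(0.90 * chrom_len - width, 0.021 * chrom_len)
                op.target_lo = float(rng.uniform(0.02 * chrom_len, hi))
            by_lg.setdefault(lg, []).append(op)
    for lst in by_lg.values():
        lst.sort(key=lambda o: o.start)
    return by_lg


def _truth_segments(cfg, ops, fbp, cm, chrom, chrom_len, lg_len):
    """Segment one (species, LG) anchor sequence into truth runs.

    Returns a list of (index_list, orientation, chromosome). Applies the
    breakpoint-margin conventions described in the module docstring.
    """
    thr_b = cfg.tau * chrom_len
    thr_c = cfg.tau * lg_len
    m = len(fbp)

    def spans_ok(idx: Sequence[int]) -> bool:
        b = fbp[list(idx)]
        c = cm[list(idx)]
        return (b.max() - b.min()) < thr_b and (c.max() - c.min()) < thr_c

    segments: list[tuple[list[int], int, str]] = []
    cur: list[int] = []
    pos = 0
    for op in ops:
        cur.extend(range(pos, op.start))
        if op.kind == "trans":
            if cur:
                segments.append((cur, 1, chrom))
            segments.append(
                (list(range(op.start, op.end + 1)), 1, op.target_chrom)
            )
            cur = []
        else:  # inversion
            size = op.end - op.start + 1
            a = 1
            while a < size and spans_ok(range(op.start, op.start + a + 1)):
                a += 1
            cur.extend(range(op.start, op.start + a))
            mid = list(range(op.start + a, op.end + 1))
            if cur:
                segments.append((cur, 1, chrom))
            if not mid:
                cur = []
            elif spans_ok(mid):
                cur = mid  # below tolerance: leads the following run
            else:
                segments.append((mid, -1, chrom))
                cur = []
        pos = op.end + 1
    cur.extend(range(pos, m))
    if cur:
        segments.append((cur, 1, chrom))
    return segments


def simulate(config: SimConfig) -> SimResult:
    """Run one simulation; all randomness derives from ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    L = cfg.chrom_length_bp
    lg_ids = [f"lg{i + 1:02d}" for i in range(cfg.n_lgs)]

    # --- ancestral map -----------------------------------------------------
    loci: list[MapLocus] = []
    abp_by_lg: list[np.ndarray] = []
    cm_by_lg: list[np.ndarray] = []
    ids_by_lg: list[list[str]] = []
    classes = list(_MARKER_CLASS_PROBS)
    probs = list(_MARKER_CLASS_PROBS.values())
    for lg_i, lg in enumerate(lg_ids):
        m = cfg.loci_per_lg
        abp = np.sort(rng.uniform(0.01 * L, 0.92 * L, size=m)).astype(np.int64)
        abp = np.maximum.accumulate(abp + np.arange(m))  # force distinct bp
        # piecewise-constant recombination rate over 5 equal-bp windows
        rates = rng.uniform(0.5, 1.5, size=5)
        edges = np.linspace(0, L, 6)
        cum = np.concatenate([[0.0], np.cumsum(rates * np.diff(edges))])
        raw = np.interp(abp, edges, cum)
        if m > 1:
            cm = (raw - raw[0]) / (raw[-1] - raw[0]) * cfg.lg_length_cM
        else:
            cm = np.zeros(1)
        # zero-recombination bins: collapse a fraction onto the previous locus
        tie = rng.random(m) < cfg.tie_fraction
        for i in range(1, m):
            if tie[i]:
                cm[i] = cm[i - 1]
        cm = np.round(cm, 6)
        mclass = rng.choice(classes, size=m, p=probs)
        ids = [f"{lg}_L{i + 1:03d}" for i in range(m)]
        for i in range(m):
            loci.append(
                MapLocus(
                    locus_id=ids[i],
                    linkage_group=lg,
                    position=float(cm[i]),
                    marker_class=str(mclass[i]),
                )
            )
        abp_by_lg.append(abp)
        cm_by_lg.append(cm)
        ids_by_lg.append(ids)
    linkage_map = build_map(loci, species_label="simulated_map")
    lg_lengths = [linkage_map.groups[lg].length for lg in lg_ids]

    species_names = [f"sp{chr(ord('A') + i)}" for i in range(cfg.n_species)]
    chromosomes: dict[str, ChromosomeSet] = {}
    locus_hits: dict[str, list[HomologyHit]] = {}
    transcript_hits: dict[str, list[HomologyHit]] = {}
    truth = SimTruth()
    ev_lo, ev_hi = cfg.evalue_range

    # per-species data needed later for transcript planting
    sp_ops: dict[str, dict[int, list[_Op]]] = {}
    sp_anchor_idx: dict[str, list[np.ndarray]] = {}
    sp_fbp: dict[str, list[np.ndarray]] = {}
    sp_truth_segments: dict[str, list[list[tuple[list[int], int, str]]]] = {}

    for sp in species_names:
        chrom_of_lg = [f"{sp}_chr{i + 1}" for i in range(cfg.n_lgs)]
        chromosomes[sp] = ChromosomeSet(
            species=sp, sizes={c: L for c in chrom_of_lg}
        )
        hits: list[HomologyHit] = []

        # decoy assignment per locus
        anch_idx: list[np.ndarray] = []
        anch_abp: list[np.ndarray] = []
        anch_cm: list[np.ndarray] = []
        decoys: list[tuple[int, int, str]] = []  # (lg, locus_idx, kind)
        for lg_i in range(cfg.n_lgs):
            u = rng.random(cfg.loci_per_lg)
            kind = np.full(cfg.loci_per_lg, "anchor", dtype=object)
            kind[u < cfg.no_hit_rate] = "none"
            band = cfg.no_hit_rate
            kind[(u >= band) & (u < band + cfg.multi_chrom_rate)] = "multi"
            band += cfg.multi_chrom_rate
            kind[(u >= band) & (u < band + cfg.weak_hit_rate)] = "weak"
            sel = np.where(kind == "anchor")[0]
            anch_idx.append(sel)
            anch_abp.append(abp_by_lg[lg_i][sel].astype(float))
            anch_cm.append(cm_by_lg[lg_i][sel])
            for j in np.where(kind != "anchor")[0]:
                if kind[j] != "none":
                    decoys.append((lg_i, int(j), str(kind[j])))

        ops_by_lg = _sample_ops(
            rng, cfg, anch_abp, anch_cm, lg_lengths, chrom_of_lg, L
        )

        fbp_by_lg: list[np.ndarray] = []
        fchrom_by_lg: list[list[str]] = []
        segs_by_lg: list[list[tuple[list[int], int, str]]] = []
        for lg_i in range(cfg.n_lgs):
            abp = anch_abp[lg_i]
            fbp = abp.copy()
            fchrom = [chrom_of_lg[lg_i]] * len(abp)
            for op in ops_by_lg.get(lg_i, []):
                run = slice(op.start, op.end + 1)
                if op.kind == "inv":
                    fbp[run] = op.span_lo + op.span_hi - abp[run]
                else:
                    fbp[run] = op.target_lo + (abp[run] - op.span_lo)
                    for k in range(op.start, op.end + 1):
                        fchrom[k] = op.target_chrom
            if cfg.jitter_sd_bp > 0 and len(abp):
                j = rng.normal(0, cfg.jitter_sd_bp, size=len(abp))
                j = np.clip(j, -cfg.jitter_max_bp, cfg.jitter_max_bp)
                fbp = fbp + j
            fbp = np.clip(np.round(fbp), 1, L - 2000).astype(np.int64)
            fbp_by_lg.append(fbp)
            fchrom_by_lg.append(fchrom)
            segs = _truth_segments(
                cfg,
                ops_by_lg.get(lg_i, []),
                fbp.astype(float),
                anch_cm[lg_i],
                chrom_of_lg[lg_i],
                L,
                lg_lengths[lg_i],
            )
            segs_by_lg.append(segs)
            ids = ids_by_lg[lg_i]
            sel = anch_idx[lg_i]
            for members, orient, chrom in segs:
                if len(members) < 2:
                    continue
                seg_cm = anch_cm[lg_i][members]
                seg_bp = fbp[members]
                if len(set(seg_cm.tolist())) < 2 or len(set(seg_bp.tolist())) < 2:
                    orient = 0
                truth.blocks.append(
                    TruthBlock(
                        species=sp,
                        lg_id=lg_ids[lg_i],
                        chromosome=chrom,
                        locus_ids=tuple(ids[sel[k]] for k in members),
                        orientation=orient,
                    )
                )
            # emit anchor hits
            for k in range(len(sel)):
                q = ids[sel[k]]
                ev = _draw_evalue(rng, ev_lo, ev_hi)
                bs = float(200 + rng.uniform(0, 300))
                alen = int(rng.integers(150, 301))
                h = _make_hit(rng, q, fchrom[k], int(fbp[k]), ev, bs, alen)
                hits.append(HomologyHit(**{**asdict(h), "species": sp}))
                if rng.random() < cfg.extra_hit_rate:
                    bp2 = int(rng.uniform(0.01 * L, 0.90 * L))
                    h2 = _make_hit(
                        rng, q, fchrom[k], bp2,
                        min(ev * 10, 9e-11), bs - float(rng.uniform(10, 100)),
                        alen,
                    )
                    hits.append(HomologyHit(**{**asdict(h2), "species": sp}))

        # decoy hits
        for lg_i, j, kind in decoys:
            q = ids_by_lg[lg_i][j]
            if kind == "multi":
                c1, c2 = rng.choice(cfg.n_lgs, size=2, replace=False)
                for c in (c1, c2):
                    bp = int(rng.uniform(0.01 * L, 0.90 * L))
                    h = _make_hit(
                        rng, q, chrom_of_lg[int(c)], bp,
                        _draw_evalue(rng, ev_lo, ev_hi),
                        float(150 + rng.uniform(0, 200)), 200,
                    )
                    hits.append(HomologyHit(**{**asdict(h), "species": sp}))
            else:  # weak: significant-looking position, hopeless e-value
                bp = int(rng.uniform(0.01 * L, 0.90 * L))
                h = _make_hit(
                    rng, q, chrom_of_lg[lg_i], bp,
                    float(10 ** rng.uniform(-9, -2)),
                    float(40 + rng.uniform(0, 30)), 120,
                )
                hits.append(HomologyHit(**{**asdict(h), "species": sp}))

        locus_hits[sp] = hits
        sp_ops[sp] = ops_by_lg
        sp_anchor_idx[sp] = anch_idx
        sp_fbp[sp] = fbp_by_lg
        sp_truth_segments[sp] = segs_by_lg

    # --- transcripts -------------------------------------------------------
    ref_sp = species_names[0]
    guard = 2.0 * cfg.jitter_max_bp + 5.0

    def plantable_pairs(min_size: int, max_size: Optional[int] = None):
        """(lg_i, anchor-seq idx k) pairs (k, k+1) inside one ref truth block."""
        out = []
        for lg_i in range(cfg.n_lgs):
            abp = None
            for members, _orient, _chrom in sp_truth_segments[ref_sp][lg_i]:
                n = len(members)
                if n < min_size or (max_size is not None and n > max_size):
                    continue
                mem = set(members)
                for k in members:
                    if k + 1 in mem:
                        if abp is None:
                            sel = sp_anchor_idx[ref_sp][lg_i]
                            abp = abp_by_lg[lg_i][sel].astype(float)
                        if abp[k + 1] - abp[k] > 2 * guard + 20:
                            out.append((lg_i, k, n))
        return out

    big_pairs = plantable_pairs(3)
    small_pairs = plantable_pairs(2, 2)

    for sp in species_names:
        transcript_hits[sp] = []
    cat_probs = [
        ("in_block", 0.55),
        ("small_block", 0.10),
        ("outside", 0.15),
        ("multi_chrom", 0.10),
        ("weak", 0.10),
    ]
    cum = np.cumsum([p for _, p in cat_probs])

    def transform_point(sp: str, lg_i: int, t_abp: float) -> tuple[str, int]:
        chrom = f"{sp}_chr{lg_i + 1}"
        for op in sp_ops[sp].get(lg_i, []):
            if op.span_lo <= t_abp <= op.span_hi:
                if op.kind == "inv":
                    return chrom, int(op.span_lo + op.span_hi - t_abp)
                return op.target_chrom, int(op.target_lo + (t_abp - op.span_lo))
        return chrom, int(t_abp)

    for ti in range(cfg.n_transcripts):
        q = f"T{ti + 1:04d}"
        u = rng.random()
        cat = cat_probs[int(np.searchsorted(cum, u))][0]
        if cat == "small_block" and not small_pairs:
            cat = "in_block"
        if cat == "in_block" and not big_pairs:
            cat = "outside"
        alen = int(rng.integers(400, 1201))
        if cat in ("in_block", "small_block"):
            pool = big_pairs if cat == "in_block" else small_pairs
            lg_i, k, nblock = pool[int(rng.integers(len(pool)))]
            sel = sp_anchor_idx[ref_sp][lg_i]
            abp = abp_by_lg[lg_i][sel].astype(float)
            cmv = cm_by_lg[lg_i][sel]
            t_abp = float(rng.uniform(abp[k] + guard, abp[k + 1] - guard))
            true_cm = float((cmv[k] + cmv[k + 1]) / 2)
            truth.transcripts[q] = TranscriptTruth(
                q, cat, lg_id=lg_ids[lg_i], cm=true_cm, block_n_loci=nblock
            )
            for sp in species_names:
                chrom, bp = transform_point(sp, lg_i, t_abp)
                h = _make_hit(
                    rng, q, chrom, bp, _draw_evalue(rng, ev_lo, ev_hi),
                    float(300 + rng.uniform(0, 500)), alen,
                )
                transcript_hits[sp].append(HomologyHit(**{**asdict(h), "species": sp}))
        elif cat == "outside":
            truth.transcripts[q] = TranscriptTruth(q, cat)
            for sp in species_names:
                lg_i = int(rng.integers(cfg.n_lgs))
                bp = int(rng.uniform(0.955 * L, 0.985 * L))
                h = _make_hit(
                    rng, q, f"{sp}_chr{lg_i + 1}", bp,
                    _draw_evalue(rng, ev_lo, ev_hi),
                    float(300 + rng.uniform(0, 500)), alen,
                )
                transcript_hits[sp].append(HomologyHit(**{**asdict(h), "species": sp}))
        elif cat == "multi_chrom":
            truth.transcripts[q] = TranscriptTruth(q, cat)
            for sp in species_names:
                c1, c2 = rng.choice(cfg.n_lgs, size=2, replace=False)
                for c in (c1, c2):
                    bp = int(rng.uniform(0.01 * L, 0.90 * L))
                    h = _make_hit(
                        rng, q, f"{sp}_chr{int(c) + 1}", bp,
                        _draw_evalue(rng, ev_lo, ev_hi),
                        float(200 + rng.uniform(0, 300)), alen,
                    )
                    transcript_hits[sp].append(
                        HomologyHit(**{**asdict(h), "species": sp})
                    )
        else:  # weak: no significant hit anywhere
            truth.transcripts[q] = TranscriptTruth(q, cat)
            for sp in species_names:
                lg_i = int(rng.integers(cfg.n_lgs))
                bp = int(rng.uniform(0.01 * L, 0.90 * L))
                h = _make_hit(
                    rng, q, f"{sp}_chr{lg_i + 1}", bp,
                    float(10 ** rng.uniform(-9, -2)),
                    float(40 + rng.uniform(0, 30)), alen,
                )
                transcript_hits[sp].append(HomologyHit(**{**asdict(h), "species": sp}))

    return SimResult(
        config=cfg,
        linkage_map=linkage_map,
        chromosomes=chromosomes,
        locus_hits=locus_hits,
        transcript_hits=transcript_hits,
        truth=truth,
    )


def skeleton_map(
    n_loci: int = 2275,
    n_groups: int = 24,
    total_length_cM: float = 2105.30,
    species_label: str = "consensus_skeleton",
) -> LinkageMap:
    """Build a map skeleton with given totals: loci spread evenly within
    equal-length groups, group sizes differing by at most one locus.

    Useful for reproducing whole-map summary statistics that depend only on
    the totals (locus count, group count, summed length), not on individual
    positions.
    """
    if n_loci < n_groups or n_groups < 1:
        raise ValidationError("need at least one locus per group")
    base, extra = divmod(n_loci, n_groups)
    length = total_length_cM / n_groups
    loci = []
    for g in range(n_groups):
        lg = f"lg{g + 1:02d}"
        m = base + (1 if g < extra else 0)
        for i in range(m):
            pos = length * i / (m - 1) if m > 1 else 0.0
            loci.append(MapLocus(f"{lg}_S{i + 1:03d}", lg, pos))
    return build_map(loci, species_label=species_label)


def recovery_metrics(
    blocks: Sequence[SyntenyBlock],
    placements: Sequence[Placement],
    truth: SimTruth,
) -> RecoveryMetrics:
    """Score detected blocks and placements against simulation truth.

    A truth block is recovered when one detected block carries exactly its
    anchor set (same species, linkage group and loci). Placement recall is
    the fraction of transcripts planted inside placeable (>=3-anchor) truth
    blocks that received at least one placement whose linkage group matches
    and whose cM interval contains the true position; the false-placement
    rate is the fraction of transcripts planted outside all blocks that
    were placed anyway.
    """
    truth_keys = {
        (b.species, b.lg_id, frozenset(b.locus_ids)) for b in truth.blocks
    }
    det_keys = {
        (b.species, b.lg_id, frozenset(a.locus_id for a in b.anchors))
        for b in blocks
    }
    matched = truth_keys & det_keys
    precision = len(matched) / len(det_keys) if det_keys else 1.0
    recall = len(matched) / len(truth_keys) if truth_keys else 1.0

    by_query: dict[str, list[Placement]] = {}
    for p in placements:
        if p.query_id not in truth.transcripts:
            raise ValidationError(
                f"placement for unknown transcript {p.query_id!r}: "
                "simulation provenance mismatch"
            )
        by_query.setdefault(p.query_id, []).append(p)

    placeable = [
        t for t in truth.transcripts.values() if t.category == "in_block"
    ]
    n_ok = 0
    for t in placeable:
        for p in by_query.get(t.query_id, []):
            lo, hi = p.interval_cM
            if p.lg_id == t.lg_id and lo - 1e-6 <= t.cm <= hi + 1e-6:
                n_ok += 1
                break
    placement_recall = n_ok / len(placeable) if placeable else 1.0

    outside = [
        t for t in truth.transcripts.values() if t.category == "outside"
    ]
    n_false = sum(1 for t in outside if by_query.get(t.query_id))
    false_rate = n_false / len(outside) if outside else 0.0
    return RecoveryMetrics(
        block_precision=precision,
        block_recall=recall,
        placement_recall=placement_recall,
        false_placement_rate=false_rate,
        n_truth_blocks=len(truth_keys),
        n_detected_blocks=len(det_keys),
    )
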