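"""Shared fixtures: tiny hand-built maps/anchors and simulation helpers."""

from __future__ import annotations

import numpy as np
import pytest

from synmap import (
    Anchor,
    ChromosomeSet,
    MapLocus,
    SimConfig,
    build_map,
    detect_blocks,
    filter_significant,
    place_transcripts,
    resolve_anchors,
    simulate,
)


def anchor(locus, cm, bp, lg="lg1", species="sp", chrom="c1") -> Anchor:
    return Anchor(
        locus_id=locus, species=species, chromosome=chrom, bp=bp, lg_id=lg, cm=cm
    )


def map_for(anchors, lg_length=100.0):
    """A linkage map containing the anchors plus end markers fixing the
    group length (tolerance thresholds scale with it)."""
    loci = [
        MapLocus(a.locus_id, a.lg_id, a.cm) for a in anchors
    ]
    lgs = {a.lg_id for a in anchors}
    for lg in lgs:
        loci.append(MapLocus(f"{lg}_end0", lg, 0.0))
        loci.append(MapLocus(f"{lg}_end1", lg, lg_length))
    return build_map(loci)


def sizes_for(chrom_length=10_000, species="sp", chroms=("c1",)):
    return {species: ChromosomeSet(species, {c: chrom_length for c in chroms})}


@pytest.fixture
def simple_anchors():
    return [anchor("A", 0.0, 100), anchor("B", 5.0, 200)]


def run_analysis(result):
    """Detect blocks and place transcripts for every simulated species."""
    blocks, placements, per_species = [], [], {}
    for sp in result.species:
        sizes = result.chromosomes[sp]
        sig = filter_significant(result.locus_hits[sp])
        anchors, discards = resolve_anchors(sig, result.linkage_map, sizes)
        mapped = [a for a in anchors if a.is_mapped]
        sp_blocks = detect_blocks(
            mapped, result.linkage_map, {sp: sizes}
        )
        tsig = filter_significant(result.transcript_hits[sp])
        tanchors, _ = resolve_anchors(tsig, result.linkage_map, sizes)
        tanchors = [a for a in tanchors if not a.is_mapped]
        pl, unplaced = place_transcripts(tanchors, sp_blocks)
        blocks.extend(sp_blocks)
        placements.extend(pl)
        per_species[sp] = {
            "significant": sig,
            "anchors": mapped,
            "discards": discards,
            "blocks": sp_blocks,
            "placements": pl,
            "unplaced": unplaced,
        }
    return blocks, placements, per_species


def noise_free_config(seed: int, **overrides) -> SimConfig:
    base = dict(
        n_lgs=4,
        loci_per_lg=20,
        n_inversions=0,
        n_translocations=0,
        jitter_sd_bp=0.0,
        jitter_max_bp=0.0,
        n_transcripts=30,
        n_species=2,
        no_hit_rate=0.2,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture
def small_sim():
    return simulate(noise_free_config(11))


def random_instance(rng, n=None, with_ties=True, lg_length=100.0, chrom_length=10_000):
    """A random single-LG anchor list for oracle/property tests."""
    if n is None:
        n = int(rng.integers(2, 13))
    cm = np.sort(rng.uniform(0, lg_length, n))
    if with_ties:
        for i in range(1, n):
            if rng.random() < 0.3:
                cm[i] = cm[i - 1]
    bp = rng.integers(1, chrom_length, n)
    return [
        anchor(f"L{i:02d}", float(cm[i]), int(bp[i])) for i in range(n)
    ]
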