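"""Synteny-based placement of unmapped transcripts.

A transcript with a unique genome hit that lands inside a shared-synteny
block with more than two mapped loci inherits the cM interval between the
two block anchors bracketing it, with those loci as flanking markers.
Placements from two comparison genomes are then reconciled per transcript.
"""

from synmap import (
    Anchor,
    ChromosomeSet,
    MapLocus,
    ToleranceRule,
    build_map,
    detect_blocks,
    place_transcripts,
    reconcile_across_species,
)


def species_blocks(species, cm_bp):
    anchors = [
        Anchor(f"m{i + 1}", species, "chr1", bp, "lg22", cm)
        for i, (cm, bp) in enumerate(cm_bp)
    ]
    loci = [MapLocus(f"{species[:2]}_{a.locus_id}", "lg22", a.cm) for a in anchors]
    lmap = build_map(
        [MapLocus(a.locus_id, "lg22", a.cm) for a in anchors]
        + [MapLocus("end", "lg22", 50.0)]
    )
    sizes = {species: ChromosomeSet(species, {"chr1": 100_000})}
    return anchors, detect_blocks(anchors, lmap, sizes, ToleranceRule())


_, blocks_a = species_blocks("seabass", [(0, 1000), (5, 3000), (10, 5000), (20, 9000)])
_, blocks_b = species_blocks("tilapia", [(2, 2000), (8, 4000), (15, 7000)])

transcripts = [
    Anchor("cyp1a", "seabass", "chr1", 4000),   # between 5 and 10 cM anchors
    Anchor("cyp1a", "tilapia", "chr1", 5000),   # between 8 and 15 cM anchors
    Anchor("ahr2", "seabass", "chr1", 9500),    # outside every block
]

placements, unplaced = place_transcripts(transcripts, blocks_a + blocks_b)
for p in placements:
    print(
        f"{p.query_id} via {p.species}: lg22 {p.interval_cM[0]:.1f}-"
        f"{p.interval_cM[1]:.1f} cM between {p.left_flank} and {p.right_flank}"
    )
for u in unplaced:
    print(f"{u.query_id} via {u.species}: unplaced ({u.reason})")

print()
for rec in reconcile_across_species(placements):
    lo, hi = rec.interval_cM
    print(
        f"consolidated {rec.query_id}: {rec.flag}, lg {rec.lg_id}, "
        f"{lo:.1f}-{hi:.1f} cM from {rec.n_supporting} placements"
    )

print()
print("The consolidated interval is the intersection of the per-genome")
print("intervals: each comparison genome independently narrows the placement.")
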