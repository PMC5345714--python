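"""Shared-synteny summaries, visualisation exports, and the pipeline driver.

``summarize_blocks`` condenses one species' blocks into the usual
comparative-mapping summary: block count, mean loci per block, block sizes
on the comparison genome (Mb) and the map (cM), and the proportions of the
genome and of the map covered by blocks — proportions computed against the
total bp in chromosome-level scaffolds and the total linkage-map length.
Overlapping blocks on one chromosome (possible when blocks from different
linkage groups tile it) are summed unmerged; a warning fires in the
pathological case where summed spans exceed the genome size.

Exports: a blocks TSV, a BED6 track on the comparison genome (0-based
half-open), and circos-style link lines pairing map intervals with genome
intervals. All exports are deterministic (stable sort keys).
"""

from __future__ import annotations

import json
import logging
import os
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Optional, Sequence

from .errors import SynmapError, ValidationError
from .homology import (
    filter_significant,
    read_tabular_hits,
    resolve_anchors,
    write_anchors,
    write_discards,
)
from .map_io import (
    ChromosomeSet,
    LinkageMap,
    map_statistics,
    read_chrom_sizes,
    read_linkage_map,
)
from .placement import (
    Unplaced,
    place_transcripts,
    placement_rate,
    reconcile_across_species,
    write_consolidated,
    write_placements,
    write_unplaced,
)
from .synteny import (
    SyntenyBlock,
    ToleranceRule,
    blocks_overlap_check,
    detect_blocks,
)

logger = logging.getLogger("synmap")

#: distinguishable colors for circos link tracks, assigned per species
_PALETTE = ("red", "blue", "teal", "green", "dgrey", "purple", "orange", "black")


@dataclass(frozen=True)
class SyntenySummary:
    """Per-species summary of shared-synteny blocks."""

    species: str
    n_hits: int  # queries resolved to single-chromosome anchors
    n_blocks: int
    mean_loci_per_block: float
    mean_comparison_block_size_mb: float
    total_comparison_block_size_mb: float
    mean_map_block_size_cm: float
    total_map_block_size_cm: float
    proportion_genome_in_blocks: float
    proportion_map_in_blocks: float


def summarize_blocks(
    blocks: Sequence[SyntenyBlock],
    sizes: ChromosomeSet,
    map_total_cM: float,
    n_anchors: int,
) -> SyntenySummary:
    """Summarise the blocks of one comparison species."""
    species = sizes.species
    if any(b.species != species for b in blocks):
        raise ValidationError("summarize_blocks expects blocks of one species")
    n = len(blocks)
    if n == 0:
        return SyntenySummary(species, n_anchors, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    total_bp = sum(b.genome_size_bp for b in blocks)
    total_cm = sum(b.map_size_cM for b in blocks)
    if total_bp > sizes.total_bp:
        warnings.warn(
            f"{species}: summed block spans ({total_bp} bp) exceed the "
            f"genome size ({sizes.total_bp} bp); overlapping blocks are "
            "summed unmerged",
            stacklevel=2,
        )
    return SyntenySummary(
        species=species,
        n_hits=n_anchors,
        n_blocks=n,
        mean_loci_per_block=sum(b.n_loci for b in blocks) / n,
        mean_comparison_block_size_mb=total_bp / n / 1e6,
        total_comparison_block_size_mb=total_bp / 1e6,
        mean_map_block_size_cm=total_cm / n,
        total_map_block_size_cm=total_cm,
        proportion_genome_in_blocks=total_bp / sizes.total_bp,
        proportion_map_in_blocks=total_cm / map_total_cM if map_total_cM else 0.0,
    )


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage rounded for presentation (e.g. 227 of 724 -> 31.4)."""
    if total <= 0:
        raise ValidationError("percent: total must be positive")
    return round(100.0 * count / total, ndigits)


def reference_assembly_summary(
    n_contigs: int, total_bp: int, genome_size_bp: float
) -> dict[str, float]:
    """Mean contig size and fraction of the genome covered by a reduced-
    representation reference, from its contig count and total length."""
    if n_contigs <= 0 or genome_size_bp <= 0:
        raise ValidationError("contig count and genome size must be positive")
    return {
        "mean_contig_size_bp": round(total_bp / n_contigs, 1),
        "genome_coverage_percent": round(100.0 * total_bp / genome_size_bp, 2),
    }


# ---------------------------------------------------------------------------
# exports

BLOCK_COLUMNS = (
    "block_id", "species", "lg", "chromosome", "n_loci", "cm_start",
    "cm_end", "bp_start", "bp_end", "orientation", "locus_ids",
)


def write_blocks(blocks: Sequence[SyntenyBlock], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(BLOCK_COLUMNS) + "\n")
        for b in sorted(
            blocks, key=lambda b: (b.species, b.lg_id, b.map_span_cM, b.block_id)
        ):
            fh.write(
                "\t".join(
                    [
                        b.block_id,
                        b.species,
                        b.lg_id,
                        b.chromosome,
                        str(b.n_loci),
                        f"{b.map_span_cM[0]:.6f}",
                        f"{b.map_span_cM[1]:.6f}",
                        str(b.genome_span_bp[0]),
                        str(b.genome_span_bp[1]),
                        str(b.orientation),
                        ",".join(a.locus_id for a in b.anchors),
                    ]
                )
                + "\n"
            )


def export_blocks_bed(blocks: Sequence[SyntenyBlock], path) -> None:
    """BED6 on the comparison genome: 0-based half-open, strand from
    orientation (0 -> '.')."""
    strand = {1: "+", -1: "-", 0: "."}
    with open(path, "w") as fh:
        for b in sorted(
            blocks,
            key=lambda b: (b.species, b.chromosome, b.genome_span_bp, b.block_id),
        ):
            fh.write(
                f"{b.chromosome}\t{b.genome_span_bp[0] - 1}\t"
                f"{b.genome_span_bp[1]}\t{b.block_id}\t{b.n_loci}\t"
                f"{strand[b.orientation]}\n"
            )


def export_circos_links(blocks: Sequence[SyntenyBlock], path) -> None:
    """Circos link lines: map interval <-> genome interval, colored per
    species (palette assigned over the sorted species set)."""
    species = sorted({b.species for b in blocks})
    color = {sp: _PALETTE[i % len(_PALETTE)] for i, sp in enumerate(species)}
    with open(path, "w") as fh:
        for b in sorted(
            blocks, key=lambda b: (b.species, b.lg_id, b.map_span_cM, b.block_id)
        ):
            fh.write(
                f"{b.lg_id} {b.map_span_cM[0]:.4f} {b.map_span_cM[1]:.4f} "
                f"{b.chromosome} {b.genome_span_bp[0]} {b.genome_span_bp[1]} "
                f"color={color[b.species]}\n"
            )


def summaries_to_tsv(summaries: Sequence[SyntenySummary], path) -> None:
    cols = list(SyntenySummary.__dataclass_fields__)
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in sorted(summaries, key=lambda s: s.species):
            d = asdict(s)
            fh.write(
                "\t".join(
                    f"{d[c]:.6g}" if isinstance(d[c], float) else str(d[c])
                    for c in cols
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# pipeline driver


@dataclass
class SpeciesInput:
    """Paths describing one comparison species."""

    name: str
    chrom_sizes: str
    locus_hits: str
    transcript_hits: Optional[str] = None


@dataclass
class PipelineConfig:
    map_path: str
    species: list[SpeciesInput]
    outdir: str
    tau: float = 0.025
    evalue: float = 1e-10
    min_placement_loci: int = 3

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            species = [SpeciesInput(**s) for s in raw.pop("species")]
            return cls(species=species, **raw)
        except (KeyError, TypeError) as exc:
            raise SynmapError(f"bad pipeline config {path}: {exc}") from exc


@dataclass
class PipelineResult:
    blocks: list
    summaries: list[SyntenySummary]
    placements: list
    consolidated: list
    log: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """End-to-end run: anchors -> blocks -> summaries -> placements -> exports.

    Writes all artifact tables under ``config.outdir`` and returns the
    in-memory results with a structured log of counts at every filter
    stage. Deterministic: identical inputs give byte-identical outputs.
    """
    os.makedirs(config.outdir, exist_ok=True)
    log: dict = {"stages": {}}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except SynmapError as exc:
            raise SynmapError(f"[{name}] {exc}") from exc

    linkage_map = stage("read-map", read_linkage_map, config.map_path)
    log["stages"]["map"] = {
        "n_loci": linkage_map.n_loci,
        "n_groups": linkage_map.n_groups,
        "total_length_cM": round(linkage_map.total_length, 3),
    }
    stats = map_statistics(linkage_map)
    rule = ToleranceRule(tau=config.tau)

    all_blocks = []
    all_anchors = []
    all_placements = []
    all_unplaced = []
    summaries = []
    sizes_by_species: dict[str, ChromosomeSet] = {}
    transcript_ids: set[str] = set()

    for sp in sorted(config.species, key=lambda s: s.name):
        sizes = stage("chrom-sizes", read_chrom_sizes, sp.chrom_sizes, sp.name)
        sizes_by_species[sp.name] = sizes
        hits = stage("read-hits", read_tabular_hits, sp.locus_hits, sp.name)
        significant = filter_significant(hits, config.evalue)
        anchors, discards = stage(
            "resolve-anchors", resolve_anchors, significant, linkage_map, sizes
        )
        mapped = [a for a in anchors if a.is_mapped]
        all_anchors.extend(mapped)
        blocks = stage(
            "detect-blocks", detect_blocks, mapped, linkage_map,
            {sp.name: sizes}, rule,
        )
        all_blocks.extend(blocks)
        summaries.append(
            summarize_blocks(blocks, sizes, stats.total_length_cM, len(mapped))
        )
        splog = {
            "hits": len(hits),
            "significant": len(significant),
            "anchors": len(mapped),
            "discards": len(discards),
            "blocks": len(blocks),
            "anchors_in_blocks": sum(b.n_loci for b in blocks),
        }
        write_discards(
            discards, os.path.join(config.outdir, f"{sp.name}.discards.tsv")
        )

        if sp.transcript_hits:
            thits = stage(
                "read-transcript-hits", read_tabular_hits,
                sp.transcript_hits, sp.name,
            )
            tsig = filter_significant(thits, config.evalue)
            tanchors, tdiscards = stage(
                "resolve-transcripts", resolve_anchors, tsig, linkage_map, sizes
            )
            tanchors = [a for a in tanchors if not a.is_mapped]
            transcript_ids |= {h.query_id for h in thits}
            placements, unplaced = stage(
                "place", place_transcripts, tanchors, blocks,
                config.min_placement_loci,
            )
            all_placements.extend(placements)
            all_unplaced.extend(unplaced)
            splog.update(
                {
                    "transcript_hits": len(thits),
                    "transcript_anchors": len(tanchors),
                    "transcript_multi_chromosome": len(tdiscards),
                    "placements": len(placements),
                }
            )
            all_unplaced.extend(
                Unplaced(d.query_id, d.species, d.reason) for d in tdiscards
            )
        log["stages"][sp.name] = splog
        logger.info("species %s: %s", sp.name, splog)

    overlap = blocks_overlap_check(all_blocks, all_anchors)
    log["overlap"] = {
        "disjoint": overlap.disjoint,
        "coverage_by_species": {
            k: round(v, 4) for k, v in overlap.coverage_by_species.items()
        },
    }

    consolidated = reconcile_across_species(all_placements)
    if transcript_ids:
        summary = placement_rate(all_placements, transcript_ids)
        log["placement"] = {
            "n_transcripts": summary.n_transcripts,
            "n_placed": summary.n_placed,
            "percent_placed": summary.percent_placed,
        }

    out = config.outdir
    write_anchors(all_anchors, os.path.join(out, "anchors.tsv"))
    write_blocks(all_blocks, os.path.join(out, "blocks.tsv"))
    export_blocks_bed(all_blocks, os.path.join(out, "blocks.bed"))
    export_circos_links(all_blocks, os.path.join(out, "circos_links.txt"))
    summaries_to_tsv(summaries, os.path.join(out, "synteny_summary.tsv"))
    write_placements(all_placements, os.path.join(out, "placements.tsv"))
    write_unplaced(all_unplaced, os.path.join(out, "unplaced.tsv"))
    write_consolidated(consolidated, os.path.join(out, "consolidated.tsv"))
    with open(os.path.join(out, "pipeline_log.json"), "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        blocks=all_blocks,
        summaries=summaries,
        placements=all_placements,
        consolidated=consolidated,
        log=log,
    )
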