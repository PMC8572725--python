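"""End-to-end analysis on the synthetic world, with truth-recovery scores.

Runs every stage on one seeded world: differential expression and
derepressed-gene calling, ChIC window quantification with domain
calling, promoter motif enrichment, accessibility grouping, DamID group
comparison, and 3D focus positioning. Returns the result tables plus
summary statistics comparing each stage's output with the planted truth.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from k9me import accessibility, chic, expression, motifs, position, synthdata
from k9me.genomic_io import write_intervals


def interval_jaccard(a, b, chrom_lengths) -> float:
    """Per-base Jaccard overlap between two interval sets."""
    inter = union = 0
    for chrom, L in chrom_lengths.items():
        pa = np.zeros(L, bool)
        pb = np.zeros(L, bool)
        for iv in a:
            if iv.chrom == chrom:
                pa[iv.start : iv.end] = True
        for iv in b:
            if iv.chrom == chrom:
                pb[iv.start : iv.end] = True
        inter += int((pa & pb).sum())
        union += int((pa | pb).sum())
    return inter / union if union else 1.0


def run_full_analysis(
    seed: int,
    outdir: str | Path | None = None,
    n_nuclei: int = 20,
) -> dict[str, Any]:
    """Generate a seeded world, run all stages, score truth recovery.

    When ``outdir`` is given the main result tables are written there as
    TSV/BED (deterministically for a fixed seed).
    """
    config = synthdata.SimulationConfig(seed=seed)
    world = synthdata.generate_world(config)
    out: dict[str, Any] = {"config": config, "world": world}

    # --- expression: derepression calling vs planted truth
    cm = synthdata.simulate_expression_counts(world)
    de = expression.differential_expression(cm, ("met-2", "WT"))
    called = expression.call_derepressed(de, fdr_max=0.01, log2fc_min=2.0)
    truth_set = set(world.genes_of_class("silenced_derepressible"))
    background = set(world.truth.index) - truth_set
    out["de_table"] = de.table
    out["derepressed"] = called
    out["derepression_sensitivity"] = (
        len(truth_set & called.gene_ids) / len(truth_set) if truth_set else np.nan
    )
    out["derepression_background_fpr"] = (
        len(background & called.gene_ids) / len(background) if background else np.nan
    )

    # --- ChIC: WT H3K9me3 domains vs planted domains
    frags = synthdata.simulate_chic_fragments(world, "H3K9me3", genotypes=["WT"])
    ctrl = synthdata.simulate_chic_fragments(world, "MNase", genotypes=["WT"])
    template = chic.tile_genome(world.genome, 500)
    ab_tracks = [chic.count_fragments(f, template) for f in frags["WT"]]
    control = chic.count_fragments(ctrl["WT"][0], template)
    ratio = chic.control_normalize(ab_tracks, control)
    domains = chic.call_domains(ratio, fc_min=2.0, min_run=2, mark="H3K9me3")
    out["ratio_track"] = ratio
    out["domains"] = domains
    out["domain_jaccard"] = interval_jaccard(
        domains.domains, world.domains, world.chrom_lengths
    )

    # --- motifs: enrichment on the *called* derepressed set
    hits = motifs.scan_pwm_set(world.genome, world.pwms)
    promoters = motifs.promoter_windows(
        world.genes, chrom_lengths=world.chrom_lengths
    )
    lengths = {p.name: p.length for p in world.pwms}
    counts = motifs.promoter_hit_counts(hits, promoters, lengths)
    genome_hits = {tf: len(h) for tf, h in hits.items()}
    enrichment = motifs.motif_enrichment(counts, called, genome_hits)
    planted = world.planted_tf_names
    decoys = [tf for tf in enrichment.index if tf not in planted]
    out["motif_enrichment"] = enrichment
    out["planted_tfs"] = planted
    out["planted_enrichment_min"] = float(
        enrichment.loc[planted, "log2_enrichment"].min()
    )
    out["decoy_enrichment_max"] = float(
        enrichment.loc[decoys, "log2_enrichment"].max()
    )
    out["planted_all_enriched"] = bool(enrichment.loc[planted, "enriched"].all())
    out["decoys_enriched"] = int(enrichment.loc[decoys, "enriched"].sum())

    # --- accessibility: Group A/B/C classification vs planted labels
    peaks, peak_counts, damid_counts = synthdata.simulate_accessibility_and_damid(
        world
    )
    de_double = expression.differential_expression(cm, ("met-2 set-25", "WT"))
    gene_ids = [g.gene_id for g in world.genes]
    promoter_cm = expression.CountMatrix(
        counts=peak_counts.counts.loc[gene_ids], samples=peak_counts.samples
    )
    acc_de = accessibility.promoter_accessibility(
        promoter_cm, ("met-2 set-25", "WT")
    )
    groups = accessibility.classify_groups(de_double, acc_de)
    out["groups"] = groups
    agreement = {}
    for grp in "ABC":
        truth_g = set(world.genes_of_group(grp))
        called_g = set(groups.index[groups["group"] == grp])
        agreement[grp] = (
            len(truth_g & called_g) / len(truth_g) if truth_g else np.nan
        )
    out["group_agreement"] = agreement

    # --- DamID: Group A vs C bin distributions
    fusion, damid_control = synthdata.damid_tracks(world, damid_counts)
    damid = position.damid_bin_ratio(fusion, damid_control)
    pooled, pairwise = position.group_position_compare(
        damid, world.truth.rename(columns={"group_label": "group"}), world.genes
    )
    out["damid_track"] = damid
    out["damid_pooled"] = pooled
    out["damid_pairwise"] = pairwise
    sel = (pairwise["group_1"] == "A") & (pairwise["group_2"] == "C")
    out["damid_a_vs_c_p"] = float(pairwise.loc[sel, "pvalue"].iloc[0])
    out["damid_a_minus_c"] = float(
        np.mean(pooled["A"]) - np.mean(pooled["C"])
    )

    # --- imaging: focus recovery on rendered nuclei
    scenes = synthdata.render_nuclei(config, n_nuclei=n_nuclei)
    n_inside = n_detected = 0
    errors = []
    for sc in scenes:
        masks = position.segment_nuclei(sc.stack[0], sc.voxel_size)
        foci = position.detect_foci(
            sc.stack[1], sc.voxel_size, sigma=config.focus_sigma
        )
        records = position.focus_periphery_distance(
            masks, foci, sc.voxel_size, channel=sc.stack[1],
            sigma=config.focus_sigma,
        )
        for _, t in sc.truth.iterrows():
            if not t["inside"]:
                continue
            n_inside += 1
            best, best_d = None, np.inf
            for r in records:
                d = np.sqrt(
                    (r.z - t["z"]) ** 2 + (r.y - t["y"]) ** 2 + (r.x - t["x"]) ** 2
                )
                if d < best_d:
                    best, best_d = r, d
            if best is not None and best_d <= 2 * max(sc.voxel_size):
                n_detected += 1
                if not best.excluded:
                    errors.append(
                        abs(best.distance_to_periphery - t["true_distance"])
                    )
    out["focus_detection_rate"] = n_detected / n_inside if n_inside else np.nan
    out["focus_distance_mae"] = float(np.mean(errors)) if errors else np.nan
    out["n_planted_foci"] = n_inside

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        de.table.to_csv(outdir / "de_met-2_vs_WT.tsv", sep="\t")
        write_intervals(
            domains.domains, outdir / "h3k9me3_domains.bed",
            scores=domains.mean_enrichment,
        )
        enrichment.to_csv(outdir / "motif_enrichment.tsv", sep="\t")
        groups.to_csv(outdir / "gene_groups.tsv", sep="\t")
        pairwise.to_csv(outdir / "damid_group_tests.tsv", sep="\t", index=False)
    return out
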