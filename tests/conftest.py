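"""Shared fixtures: one synthetic world per session, plus derived data."""

from __future__ import annotations

import numpy as np
import pytest

from k9me import chic, motifs, synthdata


@pytest.fixture(scope="session")
def config() -> synthdata.SimulationConfig:
    return synthdata.SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def world(config) -> synthdata.World:
    return synthdata.generate_world(config)


@pytest.fixture(scope="session")
def expression_counts(world):
    return synthdata.simulate_expression_counts(world)


@pytest.fixture(scope="session")
def motif_scan(world):
    """Genome-wide hits for every PWM plus promoter hit counts."""
    hits = motifs.scan_pwm_set(world.genome, world.pwms)
    promoters = motifs.promoter_windows(
        world.genes, chrom_lengths=world.chrom_lengths
    )
    lengths = {p.name: p.length for p in world.pwms}
    counts = motifs.promoter_hit_counts(hits, promoters, lengths)
    return hits, promoters, counts


@pytest.fixture(scope="session")
def chic_wt_ratio(world):
    """WT H3K9me3 enrichment-over-MNase window track."""
    frags = synthdata.simulate_chic_fragments(world, "H3K9me3", genotypes=["WT"])
    ctrl = synthdata.simulate_chic_fragments(world, "MNase", genotypes=["WT"])
    template = chic.tile_genome(world.genome, 500)
    ab = [chic.count_fragments(f, template) for f in frags["WT"]]
    control = chic.count_fragments(ctrl["WT"][0], template)
    return chic.control_normalize(ab, control)


@pytest.fixture(scope="session")
def atac_damid(world):
    return synthdata.simulate_accessibility_and_damid(world)


def interval_set_jaccard(a, b, chrom_lengths) -> float:
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
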