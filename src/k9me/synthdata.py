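"""Self-contained synthetic "worm world" generator with planted truth.

Emulates the statistical structure of a tissue-specific H3K9-methylation
loss-of-function study: four genotypes (WT, met-2, set-25, met-2 set-25)
with replicates; silenced genes inside H3K9me domains, a subset of which
derepress on H3K9me loss and carry planted TF motifs in their promoters;
Group A/B/C expression-accessibility structure; periphery-biased DamID
signal for the non-decompacting (Group A) genes; and 3D two-channel
nucleus images with known focus positions.

Everything is deterministic given the config seed. Effect sizes are free
simulation parameters, not estimates of the underlying biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from k9me.chic import WindowTrack, tile_genome
from k9me.expression import CountMatrix
from k9me.genomic_io import (
    GeneModel,
    GenomeSequence,
    Interval,
    PWMatrix,
    write_fasta,
    write_gene_models_tsv,
    write_intervals,
    write_pwm_set,
)

GENOTYPES = ("WT", "met-2", "set-25", "met-2 set-25")

GENE_CLASSES = (
    "muscle_expressed",
    "silenced_derepressible",
    "silenced_stable",
    "background",
)

# stage constants for deriving independent random streams from one seed
_STREAMS = {
    "genome": 1,
    "expression": 2,
    "chic": 3,
    "atac": 4,
    "damid": 5,
    "imaging": 6,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic world; ``seed`` is mandatory."""

    seed: int
    n_chromosomes: int = 3
    chrom_length: int = 300_000
    n_genes: dict[str, int] = field(
        default_factory=lambda: {
            "muscle_expressed": 60,
            "silenced_derepressible": 60,
            "silenced_stable": 60,
            "background": 120,
        }
    )
    replicates: int = 3
    nb_dispersion: float = 0.1
    # class baseline mean counts
    baseline_expression: dict[str, float] = field(
        default_factory=lambda: {
            "muscle_expressed": 300.0,
            "silenced_derepressible": 20.0,
            "silenced_stable": 20.0,
            "background": 60.0,
        }
    )
    derepression_fc: float = 16.0
    library_size_sigma: float = 0.15
    # gene geometry
    gene_span: int = 1_500
    # motifs
    n_tfs: int = 6
    n_planted_tfs: int = 2
    motif_length: int = 8
    background_motif_copies: int = 300
    # ChIC
    chic_fragments: int = 150_000
    chic_replicates: int = 2
    chic_ratio: float = 8.0
    fragment_length: int = 150
    # repeats
    repeats_per_chromosome: int = 40
    # groups
    n_group_a: int = 40
    n_group_b: int = 20
    n_group_c: int = 30
    # accessibility
    peak_base_mean: float = 50.0
    accessibility_fc: float = 8.0
    enhancer_peaks_per_chromosome: int = 10
    # DamID
    damid_bin: int = 10_000
    damid_depth: float = 100.0
    periphery_bias_group_a: float = 2.0
    # imaging
    image_shape: tuple[int, int, int] = (32, 64, 64)  # z, y, x voxels
    voxel_size: tuple[float, float, float] = (0.2, 0.1, 0.1)  # z, y, x, um
    nucleus_radius: float = 2.0  # um
    foci_per_nucleus: int = 2
    focus_sigma: float = 0.15  # um
    snr: float = 5.0
    outside_focus_fraction: float = 0.1

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.n_genes.values()):
            raise ValueError("gene counts must be non-negative")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[stage]])
        )


@dataclass
class World:
    """Genome bundle plus planted truth."""

    config: SimulationConfig
    genome: GenomeSequence
    genes: list[GeneModel]
    repeats: list[Interval]
    pwms: list[PWMatrix]
    domains: list[Interval]  # planted H3K9me domains (merged)
    enhancer_peaks: list[Interval]
    truth: pd.DataFrame  # indexed by gene_id

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return self.genome.lengths

    def genes_of_class(self, cls: str) -> list[str]:
        return list(self.truth.index[self.truth["class"] == cls])

    def genes_of_group(self, group: str) -> list[str]:
        return list(self.truth.index[self.truth["group_label"] == group])

    @property
    def planted_tf_names(self) -> list[str]:
        names: list[str] = []
        for entry in self.truth["planted_motifs"]:
            for name in entry.split(",") if entry else []:
                if name not in names:
                    names.append(name)
        return names

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fasta")
        write_gene_models_tsv(self.genes, outdir / "genes.tsv")
        write_intervals(self.repeats, outdir / "repeats.bed")
        write_intervals(self.domains, outdir / "h3k9me_domains.bed")
        write_intervals(self.enhancer_peaks, outdir / "enhancer_peaks.bed")
        write_pwm_set(self.pwms, outdir / "pwms.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t")


# --------------------------------------------------------------------------
# world construction


def _make_pwms(config: SimulationConfig, rng: np.random.Generator) -> list[PWMatrix]:
    """Strict PWMs: consensus base weight 2, others −6, so only perfect
    consensus windows reach the score-10 threshold (max score 2L)."""
    pwms = []
    for i in range(config.n_tfs):
        consensus = rng.integers(0, 4, size=config.motif_length)
        w = np.full((4, config.motif_length), -6.0)
        w[consensus, np.arange(config.motif_length)] = 2.0
        pwms.append(PWMatrix(tf_names=[f"TF-{i + 1}"], weights=w))
    return pwms


def _merge_intervals(ivs: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for iv in sorted(ivs, key=lambda v: (v.chrom, v.start)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            last = out[-1]
            out[-1] = Interval(last.chrom, last.start, max(last.end, iv.end),
                               label=last.label)
        else:
            out.append(iv)
    return out


def generate_world(config: SimulationConfig) -> World:
    """Build the synthetic genome, annotation, PWMs, domains and truth.

    Genes are laid out on a per-chromosome grid in contiguous class
    blocks (muscle, derepressible, stable, background) over the first 80%
    of each chromosome; the gene-free tail hosts intergenic enhancer
    peaks. Planted TF consensus sequences are embedded at recorded
    promoter offsets of every silenced_derepressible gene and scattered
    uniformly genome-wide (all motifs) so genome-wide abundance is
    realistic for decoys too.
    """
    rng = config.rng("genome")
    n_total = sum(config.n_genes.values())
    per_chrom = -(-n_total // config.n_chromosomes)
    genic_span = int(config.chrom_length * 0.8)
    spacing = genic_span // (per_chrom + 1)
    if spacing < config.gene_span + 200:
        raise ValueError(
            f"genes do not fit: spacing {spacing} < span {config.gene_span} + 200"
        )

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    seqs = {
        c: rng.integers(0, 4, size=config.chrom_length) for c in chrom_names
    }

    # per-chromosome class blocks, proportional to global class counts
    class_sequence: list[str] = []
    for cls in GENE_CLASSES:
        class_sequence.extend([cls] * config.n_genes[cls])

    genes: list[GeneModel] = []
    rows = []
    gi = 0
    for ci, chrom in enumerate(chrom_names):
        # classes for this chromosome: round-robin slices keep blocks
        classes_here = sorted(
            class_sequence[ci::config.n_chromosomes],
            key=GENE_CLASSES.index,
        )
        for k in range(len(classes_here)):
            start = 2_000 + (k + 1) * spacing
            strand = "+" if k % 2 == 0 else "-"
            exons = ((start, start + 600), (start + 900, start + config.gene_span))
            gid = f"g{gi + 1:04d}"
            g = GeneModel(gid, chrom, strand, exons)
            genes.append(g)
            rows.append(
                {
                    "gene_id": gid,
                    "class": classes_here[k],
                    "chrom": chrom,
                    "strand": strand,
                    "tss": g.tss,
                    "span_start": start,
                    "span_end": start + config.gene_span,
                }
            )
            gi += 1
    truth = pd.DataFrame(rows).set_index("gene_id")

    # H3K9me domains: silenced gene neighbourhoods, merged
    silenced = truth[truth["class"].isin(["silenced_derepressible", "silenced_stable"])]
    domain_parts = [
        Interval(
            r["chrom"],
            max(0, int(r["span_start"]) - 1_000),
            min(config.chrom_length, int(r["span_end"]) + 1_000),
            label="H3K9me",
        )
        for _, r in silenced.iterrows()
    ]
    domains = _merge_intervals(domain_parts)
    truth["h3k9_domain"] = truth["class"].isin(
        ["silenced_derepressible", "silenced_stable"]
    )

    # Group labels: A/B from derepressible (block order), C from stable
    truth["group_label"] = "none"
    derep = [g for g in truth.index if truth.at[g, "class"] == "silenced_derepressible"]
    for g in derep[: config.n_group_a]:
        truth.at[g, "group_label"] = "A"
    for g in derep[config.n_group_a : config.n_group_a + config.n_group_b]:
        truth.at[g, "group_label"] = "B"
    stable = [g for g in truth.index if truth.at[g, "class"] == "silenced_stable"]
    for g in stable[: config.n_group_c]:
        truth.at[g, "group_label"] = "C"

    truth["periphery_bias"] = np.where(
        truth["group_label"] == "A", config.periphery_bias_group_a, 0.0
    )
    truth["baseline_expression"] = truth["class"].map(config.baseline_expression)
    truth["derepression_fc"] = np.where(
        truth["class"] == "silenced_derepressible", config.derepression_fc, 1.0
    )

    # PWMs and motif planting
    pwms = _make_pwms(config, rng)
    base_to_code = {"A": 0, "C": 1, "G": 2, "T": 3}
    planted_pwms = pwms[: config.n_planted_tfs]
    truth["planted_motifs"] = ""
    truth["motif_offset"] = -1
    for g in genes:
        if truth.at[g.gene_id, "class"] != "silenced_derepressible":
            continue
        pwm = planted_pwms[int(rng.integers(len(planted_pwms)))]
        codes = np.array([base_to_code[b] for b in pwm.consensus])
        # two sites per promoter; counting is site-weighted downstream
        for upstream_off in (800, 1_200):
            if g.strand == "+":
                offset = g.tss - upstream_off
            else:
                offset = g.tss + upstream_off - pwm.length
            seqs[g.chrom][offset : offset + pwm.length] = codes
        truth.at[g.gene_id, "planted_motifs"] = pwm.name
        truth.at[g.gene_id, "motif_offset"] = offset

    # scatter every motif's consensus genome-wide for realistic abundance
    for pwm in pwms:
        codes = np.array([base_to_code[b] for b in pwm.consensus])
        for _ in range(config.background_motif_copies):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            pos = int(rng.integers(0, config.chrom_length - pwm.length))
            seqs[chrom][pos : pos + pwm.length] = codes

    # intergenic enhancer peaks in the gene-free tail, planted TF consensus
    enhancer_peaks: list[Interval] = []
    tail_start = genic_span + 5_000
    for chrom in chrom_names:
        for k in range(config.enhancer_peaks_per_chromosome):
            s = tail_start + k * 2_000
            e = s + 400
            if e > config.chrom_length:
                break
            peak = Interval(chrom, s, e, label=f"enh_{chrom}_{k}")
            enhancer_peaks.append(peak)
            pwm = planted_pwms[k % len(planted_pwms)]
            codes = np.array([base_to_code[b] for b in pwm.consensus])
            mid = (s + e) // 2
            seqs[chrom][mid : mid + pwm.length] = codes

    # repeats: random in the genic region (never in the enhancer tail)
    repeats: list[Interval] = []
    for chrom in chrom_names:
        for k in range(config.repeats_per_chromosome):
            length = int(rng.integers(100, 500))
            s = int(rng.integers(0, genic_span - length))
            repeats.append(Interval(chrom, s, s + length, label=f"rep_{chrom}_{k}"))
    repeats.sort(key=lambda r: (r.chrom, r.start))

    genome = GenomeSequence(
        {c: "".join("ACGT"[i] for i in seqs[c]) for c in chrom_names}
    )
    return World(
        config=config,
        genome=genome,
        genes=genes,
        repeats=repeats,
        pwms=pwms,
        domains=domains,
        enhancer_peaks=enhancer_peaks,
        truth=truth,
    )


# --------------------------------------------------------------------------
# count simulation


def _nb_sample(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with var = m + dispersion * m^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_expression_counts(
    world: World | pd.DataFrame, config: SimulationConfig | None = None
) -> CountMatrix:
    """Genes x samples RNA-seq-like counts.

    silenced_derepressible genes have mean x derepression_fc in met-2
    and met-2 set-25 samples only (set-25 behaves like WT); counts are
    negative binomial with the configured dispersion; per-sample library
    size factors are lognormal.
    """
    truth = world.truth if isinstance(world, World) else world
    config = world.config if isinstance(world, World) else config
    if config is None:
        raise ValueError("config required when passing a bare truth table")
    rng = config.rng("expression")
    base = truth["baseline_expression"].values.astype(float)
    fc = truth["derepression_fc"].values.astype(float)
    cols = {}
    meta = []
    for genotype in GENOTYPES:
        mean = base * fc if genotype in ("met-2", "met-2 set-25") else base
        for rep in range(1, config.replicates + 1):
            lib = float(np.exp(rng.normal(0.0, config.library_size_sigma)))
            name = f"{genotype}_rep{rep}"
            cols[name] = _nb_sample(rng, mean * lib, config.nb_dispersion)
            meta.append({"sample": name, "genotype": genotype, "replicate": rep})
    counts = pd.DataFrame(cols, index=truth.index)
    samples = pd.DataFrame(meta).set_index("sample")
    return CountMatrix(counts=counts, samples=samples)


def make_null_truth(n_genes: int, baseline: float = 50.0) -> pd.DataFrame:
    """Truth table with no planted effects (for calibration runs)."""
    idx = [f"n{i + 1:05d}" for i in range(n_genes)]
    return pd.DataFrame(
        {
            "class": "background",
            "baseline_expression": baseline,
            "derepression_fc": 1.0,
        },
        index=pd.Index(idx, name="gene_id"),
    )


# --------------------------------------------------------------------------
# ChIC fragments


def _emission_regions(
    world: World, mark: str, genotype: str
) -> list[tuple[Interval, float]]:
    """Weighted regions emitting signal for a mark in a genotype.

    H3K9me2 is retained wherever H3K9me3 was (WT and set-25); H3K9me3
    needs SET-25 (full in WT, half in the met-2 single mutant, absent in
    set-25 and the double mutant); H3K27ac appears at Group C (full) and
    Group B (half) gene spans only in the met-2 set-25 double mutant.
    MNase is the uniform control.
    """
    r = world.config.chic_ratio
    if mark == "MNase":
        return []
    if mark == "H3K9me2":
        if genotype in ("WT", "set-25"):
            return [(d, r) for d in world.domains]
        return []
    if mark == "H3K9me3":
        if genotype == "WT":
            return [(d, r) for d in world.domains]
        if genotype == "met-2":
            return [(d, r / 2) for d in world.domains]
        return []
    if mark == "H3K27ac":
        if genotype != "met-2 set-25":
            return []
        out = []
        for gid in world.genes_of_group("C"):
            row = world.truth.loc[gid]
            out.append(
                (Interval(row["chrom"], int(row["span_start"]), int(row["span_end"])), r)
            )
        for gid in world.genes_of_group("B"):
            row = world.truth.loc[gid]
            out.append(
                (Interval(row["chrom"], int(row["span_start"]), int(row["span_end"])), r / 2)
            )
        return out
    raise ValueError(f"unknown mark {mark!r}")


def _sample_fragments(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    regions: list[tuple[Interval, float]],
    n_fragments: int,
    fragment_length: int,
) -> list[Interval]:
    """Sample fragment start positions with per-region rate multipliers
    over a uniform background of weight 1."""
    segments: list[tuple[str, int, int, float]] = []
    for chrom, L in chrom_lengths.items():
        cuts = sorted(
            {0, L}
            | {max(0, min(iv.start, L)) for iv, _ in regions if iv.chrom == chrom}
            | {max(0, min(iv.end, L)) for iv, _ in regions if iv.chrom == chrom}
        )
        for s, e in zip(cuts[:-1], cuts[1:]):
            w = 1.0
            for iv, weight in regions:
                if iv.chrom == chrom and iv.start <= s and e <= iv.end:
                    w = max(w, weight)
            segments.append((chrom, s, e, w))
    weights = np.array([(e - s) * w for _, s, e, w in segments])
    probs = weights / weights.sum()
    choice = rng.choice(len(segments), size=n_fragments, p=probs)
    lengths = np.clip(
        rng.normal(fragment_length, fragment_length / 10, size=n_fragments), 50, None
    ).astype(int)
    frags = []
    for idx, flen in zip(choice, lengths):
        chrom, s, e, _ = segments[idx]
        L = chrom_lengths[chrom]
        start = int(rng.integers(s, e))
        frags.append(Interval(chrom, start, min(start + int(flen), L), strand="+"))
    frags.sort(key=lambda f: (f.chrom, f.start))
    return frags


def simulate_chic_fragments(
    world: World,
    mark: str,
    genotypes: Sequence[str] = GENOTYPES,
) -> dict[str, list[list[Interval]]]:
    """Per-genotype replicate fragment sets for one mark (or the MNase
    control). Fragment starts are sampled at rate ``chic_ratio`` inside
    the mark's active regions and rate 1 outside."""
    config = world.config
    # a deterministic sub-stream per mark so marks are independent
    mark_offset = {"H3K9me2": 0, "H3K9me3": 1, "H3K27ac": 2, "MNase": 3}[mark]
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _STREAMS["chic"], mark_offset])
    )
    out: dict[str, list[list[Interval]]] = {}
    n_reps = 1 if mark == "MNase" else config.chic_replicates
    for genotype in genotypes:
        regions = _emission_regions(world, mark, genotype)
        reps = [
            _sample_fragments(
                rng,
                world.chrom_lengths,
                regions,
                config.chic_fragments,
                config.fragment_length,
            )
            for _ in range(n_reps)
        ]
        out[genotype] = reps
    return out


# --------------------------------------------------------------------------
# accessibility + DamID


def promoter_peaks(world: World) -> dict[str, Interval]:
    """One synthetic accessibility peak per gene promoter (strand-aware
    window around the TSS)."""
    peaks = {}
    for g in world.genes:
        if g.strand == "+":
            iv = Interval(g.chrom, max(0, g.tss - 300), g.tss + 100, label=g.gene_id)
        else:
            iv = Interval(g.chrom, max(0, g.tss - 100), g.tss + 300, label=g.gene_id)
        peaks[g.gene_id] = iv
    return peaks


def simulate_accessibility_and_damid(
    world: World,
) -> tuple[dict[str, Interval], CountMatrix, CountMatrix]:
    """Promoter-peak ATAC counts and DamID 10-kb bin counts.

    Group B and C promoter peaks (and planted enhancer peaks) gain
    counts by ``accessibility_fc`` in met-2 set-25 samples; Group A
    peaks are unchanged. DamID fusion counts are elevated over the
    control by 2**periphery_bias in bins containing biased (Group A)
    genes.
    """
    config = world.config
    rng = config.rng("atac")
    peaks = promoter_peaks(world)
    for p in world.enhancer_peaks:
        peaks[p.label] = p

    gain = {
        gid: config.accessibility_fc
        for gid in world.genes_of_group("B") + world.genes_of_group("C")
    }
    for p in world.enhancer_peaks:
        gain[p.label] = config.accessibility_fc

    base = np.full(len(peaks), config.peak_base_mean)
    names = list(peaks)
    cols = {}
    meta = []
    for genotype in GENOTYPES:
        mean = base.copy()
        if genotype == "met-2 set-25":
            mean = np.array(
                [config.peak_base_mean * gain.get(n, 1.0) for n in names]
            )
        for rep in range(1, config.replicates + 1):
            lib = float(np.exp(rng.normal(0.0, config.library_size_sigma)))
            name = f"{genotype}_rep{rep}"
            cols[name] = _nb_sample(rng, mean * lib, config.nb_dispersion)
            meta.append({"sample": name, "genotype": genotype, "replicate": rep})
    peak_counts = CountMatrix(
        counts=pd.DataFrame(cols, index=pd.Index(names, name="peak")),
        samples=pd.DataFrame(meta).set_index("sample"),
    )

    # DamID: per-bin bias = max periphery_bias over genes touching the bin
    rng_d = config.rng("damid")
    bins = []
    bias = []
    for chrom, L in world.chrom_lengths.items():
        n_bins = -(-L // config.damid_bin)
        b = np.zeros(n_bins)
        sub = world.truth[world.truth["chrom"] == chrom]
        for _, row in sub.iterrows():
            if row["periphery_bias"] == 0:
                continue
            first = int(row["span_start"]) // config.damid_bin
            last = (int(row["span_end"]) - 1) // config.damid_bin
            b[first : last + 1] = np.maximum(b[first : last + 1], row["periphery_bias"])
        for i in range(n_bins):
            s = i * config.damid_bin
            bins.append(f"{chrom}:{s}-{min(s + config.damid_bin, L)}")
        bias.append(b)
    bias_arr = np.concatenate(bias)
    fusion = _nb_sample(rng_d, config.damid_depth * 2.0**bias_arr, config.nb_dispersion)
    control = _nb_sample(
        rng_d, np.full(len(bias_arr), config.damid_depth), config.nb_dispersion
    )
    damid_counts = CountMatrix(
        counts=pd.DataFrame(
            {"EMR1_Dam": fusion, "GFP_Dam": control},
            index=pd.Index(bins, name="bin"),
        ),
        samples=pd.DataFrame(
            {"genotype": ["fusion", "control"]}, index=["EMR1_Dam", "GFP_Dam"]
        ),
    )
    return peaks, peak_counts, damid_counts


def damid_tracks(world: World, damid_counts: CountMatrix) -> tuple[WindowTrack, WindowTrack]:
    """Unpack the DamID bin CountMatrix into fusion/control WindowTracks."""
    config = world.config
    fusion = tile_genome(world.chrom_lengths, width=config.damid_bin)
    control = tile_genome(world.chrom_lengths, width=config.damid_bin)
    for bin_id, row in damid_counts.counts.iterrows():
        chrom, span = bin_id.split(":")
        start = int(span.split("-")[0])
        i = start // config.damid_bin
        fusion.values[chrom][i] = row["EMR1_Dam"]
        control.values[chrom][i] = row["GFP_Dam"]
    return fusion, control


# --------------------------------------------------------------------------
# imaging


@dataclass
class NucleusScene:
    """One rendered nucleus: (2, Z, Y, X) stack + truth focus table.

    Channel 0 is the nuclear envelope/volume signal, channel 1 the
    focus channel. ``truth`` has physical-unit focus centres, the
    inside/outside flag and the exact distance from each inside focus to
    the nearest background voxel centre of the ideal mask.
    """

    stack: np.ndarray
    voxel_size: tuple[float, float, float]
    nucleus_centre: tuple[float, float, float]
    nucleus_radius: float
    truth: pd.DataFrame

    def write_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(path, self.stack.astype(np.float32))


def _ideal_mask(
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
    centre: tuple[float, float, float],
    radius: float,
) -> np.ndarray:
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]) * voxel[0],
        np.arange(shape[1]) * voxel[1],
        np.arange(shape[2]) * voxel[2],
        indexing="ij",
    )
    d2 = (zz - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2
    return d2 <= radius**2


def _exact_boundary_distance(
    point: tuple[float, float, float],
    mask: np.ndarray,
    voxel: tuple[float, float, float],
) -> float:
    """Min Euclidean distance from a physical point to any background
    voxel centre (brute force over a shell around the mask)."""
    from scipy import ndimage

    background = ~mask
    # restrict to background voxels adjacent to the mask (3 voxel dilation)
    shell = background & ndimage.binary_dilation(mask, iterations=3)
    coords = np.argwhere(shell)
    phys = coords * np.array(voxel)
    d = np.sqrt(((phys - np.array(point)) ** 2).sum(axis=1))
    return float(d.min())


def render_nuclei(
    config: SimulationConfig, n_nuclei: int = 20
) -> list[NucleusScene]:
    """Render two-channel 3D nucleus stacks with planted foci.

    Channel 0: filled-sphere envelope signal; channel 1: Gaussian foci
    at recorded subvoxel centres. Poisson shot noise plus Gaussian read
    noise at the configured SNR (focus amplitude = snr * shot-noise
    scale). A configurable fraction of foci is placed outside the
    nucleus and flagged in the truth table.
    """
    if config.nucleus_radius < 3 * max(config.voxel_size):
        raise ValueError("nucleus radius must be >= 3 voxels")
    rng = config.rng("imaging")
    shape = config.image_shape
    voxel = config.voxel_size
    extent = tuple(s * v for s, v in zip(shape, voxel))
    scenes = []
    envelope_level = 50.0
    background_level = 5.0
    read_noise = 2.0
    amplitude = config.snr * np.sqrt(envelope_level + background_level) * 4.0

    for ni in range(n_nuclei):
        centre = tuple(
            e / 2 + float(rng.uniform(-0.2, 0.2)) for e in extent
        )
        mask = _ideal_mask(shape, voxel, centre, config.nucleus_radius)
        ch0 = background_level + envelope_level * mask

        ch1 = np.full(shape, background_level, dtype=float)
        zz = np.arange(shape[0]) * voxel[0]
        yy = np.arange(shape[1]) * voxel[1]
        xx = np.arange(shape[2]) * voxel[2]
        rows = []
        n_foci = config.foci_per_nucleus
        placed: list[np.ndarray] = []
        for fi in range(n_foci):
            outside = rng.uniform() < config.outside_focus_fraction
            for _attempt in range(100):
                if outside:
                    radial = config.nucleus_radius + float(rng.uniform(0.5, 1.0))
                else:
                    # keep foci off the rim so detection is unambiguous
                    radial = float(
                        rng.uniform(0, (config.nucleus_radius - 0.4) ** 3) ** (1 / 3)
                    )
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                pos = np.array(centre) + radial * direction
                in_bounds = all(
                    0.5 < p < e - 0.5 for p, e in zip(pos, extent)
                )
                separated = all(
                    np.linalg.norm(pos - q) > 6 * config.focus_sigma for q in placed
                )
                if in_bounds and separated:
                    break
            placed.append(pos)
            d2 = (
                (zz[:, None, None] - pos[0]) ** 2
                + (yy[None, :, None] - pos[1]) ** 2
                + (xx[None, None, :] - pos[2]) ** 2
            )
            ch1 += amplitude * np.exp(-d2 / (2 * config.focus_sigma**2))
            true_dist = (
                _exact_boundary_distance(tuple(pos), mask, voxel)
                if not outside
                else np.nan
            )
            rows.append(
                {
                    "nucleus": ni,
                    "focus": fi,
                    "z": pos[0],
                    "y": pos[1],
                    "x": pos[2],
                    "amplitude": amplitude,
                    "inside": not outside,
                    "true_distance": true_dist,
                }
            )

        stack = np.stack([ch0, ch1])
        noisy = rng.poisson(stack).astype(float) + rng.normal(
            0.0, read_noise, size=stack.shape
        )
        scenes.append(
            NucleusScene(
                stack=noisy,
                voxel_size=voxel,
                nucleus_centre=centre,
                nucleus_radius=config.nucleus_radius,
                truth=pd.DataFrame(rows),
            )
        )
    return scenes
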