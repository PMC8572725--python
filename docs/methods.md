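# Methods

This note documents the models, conventions and design choices behind
`k9me`, in the spirit of the methods documentation of packages such as
statsmodels or scanpy: what each procedure assumes, which parameters
matter, what the synthetic generator does and does not emulate, and
where the design was genuinely open.

## Coordinate contract

All internal coordinates are 0-based, half-open, on the forward strand.
BED is read and written natively; GFF3 (1-based, inclusive) is
converted at the I/O boundary, and the conversion is an involution.
A gene's TSS is its 5′-most exon boundary: the minimal exon start on
the + strand and the maximal exon end on the − strand. `N` bases are
allowed in sequences, but any PWM scan window containing `N` scores
−∞ and can never be a hit — a conservative choice where the field's
tools differ.

## Count normalization and transforms

Libraries are scaled by dividing each column by its total and
multiplying by the mean total across libraries, so all column totals
become equal while within-column ranks are preserved. Log transforms
add a pseudo-count of 8 before log2 to damp fold-change estimates at
low counts. The pseudo-count is applied **after** averaging replicates
(one transform per condition), and the same `(x + 8)` floor appears in
every ratio denominator (ChIC control, DamID control), which also
guards against division by zero in empty windows.

## Exact conditional binomial test

Differential calling uses a fully specified exact test rather than a
GLM: replicates of each condition are pooled on the library-scaled
counts, rounded half-up to integers, and conditioned on the total
`t = a + b`, the count `a` is Binomial(t, r) under the null, where `r`
is the proportion of the pooled total attributable to condition *a*
(0.5 for equal replicate numbers after scaling). The two-sided p-value
sums the probabilities of all outcomes no more likely than the observed
one (with a 1e-7 relative slack on pmf comparisons, as exact tests
conventionally use). FDR control is Benjamini–Hochberg.

This test is exact under Poisson sampling but **anti-conservative under
biological overdispersion**, because pooling discards between-replicate
variance. The package therefore pairs it with an effect-size filter
(log2FC > 2 for derepression calls) and the synthetic benchmarks use
large planted effects (16-fold); the FDR-calibration check is run under
Poisson noise, where the test's assumptions hold. For overdispersed
designs with many replicates, a dispersion-aware GLM is the better
instrument; this package deliberately trades that for a test whose
every value can be verified by rational-arithmetic enumeration.

Derepression thresholds default to FDR < 0.01 and log2FC > 2. The
fold-change threshold is exposed because "FC > 2" and "log2FC > 2"
denote different cuts; the default is the stricter log2 version.

## ChIC-seq enrichment and domains

The genome is tiled into 500-bp non-overlapping windows (final window
truncated). A fragment increments every window it overlaps by at least
one base, strand ignored; consequently window totals can exceed the
fragment count when fragments span boundaries, and equal it otherwise.
Antibody tracks are library-scaled together with the MNase–protein A
control, replicates are averaged after the pseudo-count, and the
per-window enrichment is `mean(antibody + 8) / (control + 8)`.

Domains are maximal runs of at least `min_run` (default 2) consecutive
windows with enrichment above `fc_min` (default 2, mirroring the
per-gene marking threshold). Both knobs are exposed since "consecutive
enrichment over the input" does not pin them numerically. Note that
after library equalization the achievable in-domain enrichment is
bounded by the domain fraction of the genome: with planted rate ratio
*r* and in-domain length fraction *f*, the expected window ratio is
`r / (r·f + (1 − f))`, which is ≈ *r* only when domains are rare. The
synthetic world's domains cover about a third of its miniature genome,
so the expected WT ratio is ≈ 2.5 — above the calling threshold, but
far from 8; tests assert the analytic expectation, not the naive rate
ratio.

Per-gene mark quantification sums window values over exon-overlapping
windows (each window once) for antibody and control and takes the same
pseudo-counted ratio; a gene is "marked" above 2. Arm/centre
annotation uses the published ce10 border coordinates; chromosome X
has a single printed border and is treated as a left-arm/centre split.

## PWM scanning and motif enrichment

Scores are direct sums of matrix entries at the matched bases — the
matrices are used as distributed, not log-odds-converted, because the
fixed score-10 rule is defined on that raw scale. The effective
threshold is `min(10, max_score)`; matrices that cannot reach 10
therefore require a perfect match. Both strands are scanned (the minus
strand via the reverse-complemented matrix) and hits are reported at
forward-strand coordinates.

Promoter windows are 1,500 bp upstream / 500 bp downstream of the TSS
for motif work and 1,000/100 bp for accessibility, strand-aware and
clipped at chromosome ends. Hit counting is site-weighted (every site
counts, overlaps included) and a hit overlapping two promoters counts
for both.

Enrichment of a gene set compares mean per-promoter hit counts in the
set against the full annotation:
`log2((rate_set + ε) / (rate_all + ε))` with `ε = 1/|universe|` so
zero-rate motifs stay finite; abundance is `log2(genome-wide hits + 1)`.
A motif is called enriched at log2 enrichment > 0.5 **and** log2
abundance > 8. Whether "genome-wide occurrence" means all genomic hits
or promoter-restricted hits is ambiguous in common usage; the
default is all genomic hits, and promoter-restricted counts are
available from the same hit table. The same machinery serves arbitrary
region sets (e.g. intergenic accessibility peaks) via
`region_hit_counts`.

## ATAC-seq conventions

The Tn5 correction shifts + strand reads to `start + 4` and − strand
reads to `(end − 1) − 5`: the − strand read's 5′ end is its last
covered base in half-open coordinates, and it moves 5′-ward
(rightward) by 5. The anchor choice for the − strand is a documented
convention — "shift by −5" alone does not determine it.

Peak feature labels follow the precedence promoter > repeat > exon >
intron > intergenic, with ≥ 1 bp overlap and intron meaning
"within the gene span but not exonic". The precedence order is this
package's tie rule; class percentages relative to genome-wide
occurrence divide the fraction of peaks in a class by the fraction of
genome bases in that class under the same precedence. Intergenic
enhancer-candidate peaks are those more than 1,500 bp from every
promoter with zero repeat overlap. Group classification is a pure
function of the two DE tables: A = expression up only,
B = both, C = accessibility up only, with accessibility-up meaning
FDR < 0.01 and log2FC > 0.

## DamID and imaging

DamID lamina association is `log2((fusion + 8)/(control + 8))` per
10-kb bin after scaling both tracks to their mean total. Library
equalization shifts the global baseline: when a fraction of bins is
biased upward, unbiased bins land below zero and the planted log2 bias
is recovered as the **difference** between biased and unbiased bins,
not as the absolute value — the group comparisons used downstream are
differences, so this is the relevant quantity. Genes map to every bin
their span overlaps; group comparisons pool bin values per group and
use the two-sided Wilcoxon rank-sum test — exact by full enumeration
of rank assignments for combined samples of ≤ 12 without ties,
otherwise the tie-corrected normal approximation with continuity
correction (the two branches agree to |Δp| < 0.02 at the boundary).

Nucleus segmentation smooths the envelope channel with an anisotropic
Gaussian (sigma in physical units, default 0.3 µm), thresholds with
Otsu, seeds a watershed at local maxima of the smoothed image and
floods inside the foreground; labels below a minimum volume are
dropped. Focus detection uses a scale-normalized Laplacian-of-Gaussian
response with per-axis sigmas honouring voxel anisotropy; the default
quality threshold is the response's median plus 8 robust standard
deviations (MAD-based), so blank channels yield nothing. Detected
centres are maximal voxels — no subvoxel fit — so localization error
is bounded by half a voxel per axis. Plateau duplicates (exactly tied
responses) are reduced to one representative per 2-sigma
neighbourhood. The periphery distance is the exact Euclidean distance
transform of the nucleus mask (anisotropic spacing honoured) sampled
at the focus voxel: the distance to the nearest background voxel
centre, which makes a boundary voxel's distance one voxel spacing.
Foci on background are flagged excluded, never silently dropped.

## The synthetic world

`SimulationConfig` defaults define a miniature study: 3 chromosomes ×
300 kb, 300 genes in four classes (60 muscle-expressed, 60 silenced
derepressible, 60 silenced stable, 120 background), four genotypes ×
3 replicates, negative binomial counts with dispersion 0.1 (variance
`m + 0.1 m²`; dispersion 0 gives Poisson for calibration), lognormal
library-size factors (σ = 0.15). Derepressible genes gain a 16-fold
mean increase in the *met-2* and *met-2 set-25* genotypes only —
*set-25* behaves like WT, encoding the observation that H3K9me2 alone
suffices for repression. Effect sizes are free parameters chosen to
make truth recovery decisive at desk scale; they are not estimates of
the biology.

Genes sit on a per-chromosome grid in contiguous class blocks over the
first 80% of each chromosome (spacing ≈ 2.4 kb, two exons per gene,
alternating strands); the gene-free tail hosts planted intergenic
enhancer peaks. H3K9me domains are merged ±1 kb neighbourhoods of the
silenced blocks. ChIC fragments are drawn with in-domain rate 8× the
background; genotype logic: H3K9me2 emitted in WT and *set-25*,
H3K9me3 in WT (half-rate in *met-2*, encoding its partial
maintenance), H3K27ac at Group C (full) and B (half) gene spans only
in the double mutant, MNase uniform. Each motif's consensus is
scattered ~300× genome-wide (so decoy abundance is realistic) and
additionally embedded twice in every derepressible promoter for the
two planted TFs; matrices are strict (consensus +2, other bases −6 per
column), so only perfect consensus windows pass the score-10 rule.
Group A/B come from the derepressible class (40/20), Group C from the
stable class (30); Group A carries a DamID periphery bias of 2 (log2).
Rendered nuclei are 2-channel 32×64×64 stacks at 0.2/0.1/0.1 µm
voxels: a filled 2-µm-radius sphere plus Gaussian foci (σ = 0.15 µm)
at recorded subvoxel centres, Poisson shot noise plus Gaussian read
noise; truth records each inside focus's exact distance to the nearest
background voxel centre of the ideal mask (brute-force, matching the
EDT's semantics), and a configurable fraction of foci is placed
outside the nucleus to exercise the exclusion rule.

What the generator does **not** emulate: read-level sequencing (no
FASTQ, mapping or duplicates), realistic worm karyotype or gene
structure, GC or mappability biases, fragment-length periodicity,
between-replicate batch structure, or optical aberrations beyond
Poisson+Gaussian noise. Passing truth-recovery tests therefore shows
the algorithms are correct and well-calibrated under the stated noise
models, not that the pipeline is robust to every artefact of real
data.

All stages draw from independent, deterministically derived
sub-streams of the single config seed, so every output — FASTA, BEDs,
count tables, TIFFs, result tables — is byte-identical across reruns
with the same seed.

## Problem sizes

Defaults keep the full pipeline fast on one core: the complete
end-to-end analysis (world, expression DE, ChIC tracks and domains,
genome-wide scans of six 8-mer PWMs on 0.9 Mb, grouping, DamID tests,
20 rendered and analysed nuclei) runs in well under a minute, and the
full test suite — including the exhaustive exact-test oracle
(all a + b ≤ 30 × three ratios), 1,000 random domain-calling tracks,
and 100 gene-set label permutations — in about half a minute.

## Known limitations

- The exact test's anti-conservatism under overdispersion, discussed
  above; it is the package's main statistical simplification.
- Enrichment ratios are depth- and composition-dependent through
  library equalization (see the domain and DamID sections); values are
  comparable within an analysis, not across designs.
- No subvoxel focus localization; distance errors are voxel-bounded.
- Peak calling is consumed, not performed: accessibility peaks enter
  as intervals.
- The promoter-overlap rule counts a hit for every overlapping
  promoter, so dense head-to-head annotations double-count sites by
  design (site-weighted counting).
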