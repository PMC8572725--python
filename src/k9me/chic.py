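"""ChIC-seq window quantification, MNase normalization and domain calling.

The genome is tiled into fixed-width non-overlapping windows (500 bp by
default), fragments are counted into every window they overlap by at
least one base (strand ignored), antibody tracks are library-scaled and
divided by the scaled MNase–protein A control with a pseudo-count of 8
in numerator and denominator, and heterochromatin domains are maximal
runs of consecutively enriched windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from k9me.expression import log2_pseudo
from k9me.genomic_io import GeneModel, GenomeSequence, Interval

logger = logging.getLogger(__name__)

#: ce10 chromosome arm/centre border coordinates. Chromosome X has a
#: single printed border, treated as a left-arm/centre split.
CE10_ARM_BORDERS: dict[str, tuple[int, ...]] = {
    "chrI": (3745632, 10809938),
    "chrII": (4708341, 11877168),
    "chrIII": (3508994, 9947268),
    "chrIV": (7317812, 12176625),
    "chrV": (8125434, 13849337),
    "chrX": (41919369,),
}
# accept common aliases
for _i, _roman in enumerate(["I", "II", "III", "IV", "V"], start=1):
    CE10_ARM_BORDERS[f"chr{_i}"] = CE10_ARM_BORDERS[f"chr{_roman}"]
    CE10_ARM_BORDERS[_roman] = CE10_ARM_BORDERS[f"chr{_roman}"]
    CE10_ARM_BORDERS[str(_i)] = CE10_ARM_BORDERS[f"chr{_roman}"]
CE10_ARM_BORDERS["X"] = CE10_ARM_BORDERS["chrX"]


@dataclass
class WindowTrack:
    """Fixed-width tiling with one value per window.

    ``values[chrom]`` is parallel to the tiling of that chromosome:
    windows [0,w), [w,2w), ... with a final truncated window. Values are
    counts or enrichment ratios, always >= 0.
    """

    width: int
    chrom_lengths: dict[str, int]
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, L in self.chrom_lengths.items():
            n = n_windows(L, self.width)
            if chrom not in self.values:
                raise ValueError(f"missing values for {chrom}")
            if len(self.values[chrom]) != n:
                raise ValueError(
                    f"{chrom}: expected {n} windows, got {len(self.values[chrom])}"
                )

    def same_tiling(self, other: "WindowTrack") -> bool:
        return self.width == other.width and self.chrom_lengths == other.chrom_lengths

    def windows(self, chrom: str) -> list[Interval]:
        L = self.chrom_lengths[chrom]
        return [
            Interval(chrom, s, min(s + self.width, L))
            for s in range(0, L, self.width)
        ]

    @property
    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def flat(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in sorted(self.values)])

    def write_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chrom_lengths:
                L = self.chrom_lengths[chrom]
                for i, v in enumerate(self.values[chrom]):
                    s = i * self.width
                    fh.write(f"{chrom}\t{s}\t{min(s + self.width, L)}\t{v:g}\n")


@dataclass
class DomainSet:
    """Called heterochromatin domains with per-domain mean enrichment."""

    mark: str
    domains: list[Interval]
    mean_enrichment: list[float]

    def __len__(self) -> int:
        return len(self.domains)


def n_windows(length: int, width: int) -> int:
    return -(-length // width)  # ceil division


def tile_genome(
    genome: GenomeSequence | dict[str, int], width: int = 500
) -> WindowTrack:
    """Empty (all-zero) track tiling each chromosome into ``width``-bp windows."""
    if width < 1:
        raise ValueError("width must be >= 1")
    lengths = genome.lengths if isinstance(genome, GenomeSequence) else dict(genome)
    values = {c: np.zeros(n_windows(L, width)) for c, L in lengths.items()}
    return WindowTrack(width=width, chrom_lengths=lengths, values=values)


def count_fragments(
    fragments: Sequence[Interval],
    template: WindowTrack,
) -> WindowTrack:
    """Count fragments into windows; a fragment increments every window it
    overlaps by >= 1 bp. Strand is ignored. Fragments on unknown
    chromosomes are skipped (logged)."""
    w = template.width
    values = {c: np.zeros_like(v) for c, v in template.values.items()}
    skipped = 0
    for frag in fragments:
        if frag.chrom not in values:
            skipped += 1
            continue
        L = template.chrom_lengths[frag.chrom]
        first = frag.start // w
        last = min(frag.end - 1, L - 1) // w
        values[frag.chrom][first : last + 1] += 1
    if skipped:
        logger.warning("count_fragments: skipped %d fragments on unknown chromosomes", skipped)
    return WindowTrack(width=w, chrom_lengths=template.chrom_lengths, values=values)


def _scale_tracks(tracks: Sequence[WindowTrack]) -> list[WindowTrack]:
    """Library-scale window tracks: divide by own total, multiply by the
    mean total across tracks (the count-table normalization applied to
    window totals)."""
    totals = np.array([t.total for t in tracks], dtype=float)
    if np.any(totals == 0):
        raise ValueError("zero-total track cannot be library-scaled")
    mean_total = totals.mean()
    out = []
    for t, tot in zip(tracks, totals):
        out.append(
            WindowTrack(
                width=t.width,
                chrom_lengths=t.chrom_lengths,
                values={c: v * (mean_total / tot) for c, v in t.values.items()},
            )
        )
    return out


def control_normalize(
    ab_tracks: Sequence[WindowTrack],
    control: WindowTrack,
    pseudo: float = 8.0,
) -> WindowTrack:
    """Per-window (mean of pseudo-counted scaled antibody) / (pseudo-counted
    scaled MNase control) enrichment ratio."""
    for t in ab_tracks:
        if not t.same_tiling(control):
            raise ValueError("antibody/control tiling mismatch")
    scaled = _scale_tracks(list(ab_tracks) + [control])
    ab_scaled, ctrl_scaled = scaled[:-1], scaled[-1]
    values = {}
    for chrom in control.chrom_lengths:
        ab_mean = np.mean([t.values[chrom] + pseudo for t in ab_scaled], axis=0)
        values[chrom] = ab_mean / (ctrl_scaled.values[chrom] + pseudo)
    return WindowTrack(
        width=control.width, chrom_lengths=control.chrom_lengths, values=values
    )


def call_domains(
    ratio: WindowTrack,
    fc_min: float = 2.0,
    min_run: int = 2,
    mark: str = "H3K9me",
) -> DomainSet:
    """Maximal runs of >= ``min_run`` consecutive windows with ratio > fc_min,
    merged into one interval per run."""
    domains: list[Interval] = []
    means: list[float] = []
    w = ratio.width
    for chrom in ratio.chrom_lengths:
        vals = ratio.values[chrom]
        L = ratio.chrom_lengths[chrom]
        enriched = vals > fc_min
        i = 0
        n = len(vals)
        while i < n:
            if enriched[i]:
                j = i
                while j + 1 < n and enriched[j + 1]:
                    j += 1
                if j - i + 1 >= min_run:
                    start = i * w
                    end = min((j + 1) * w, L)
                    domains.append(Interval(chrom, start, end, label=mark))
                    means.append(float(vals[i : j + 1].mean()))
                i = j + 1
            else:
                i += 1
    return DomainSet(mark=mark, domains=domains, mean_enrichment=means)


def _exon_overlap_count(track: WindowTrack, gene: GeneModel) -> float:
    """Sum of window values over windows overlapping the gene's exons,
    each overlapped window counted once."""
    w = track.width
    vals = track.values[gene.chrom]
    L = track.chrom_lengths[gene.chrom]
    hit = np.zeros(len(vals), dtype=bool)
    for s, e in gene.exons:
        first = s // w
        last = min(e - 1, L - 1) // w
        hit[first : last + 1] = True
    return float(vals[hit].sum())


def gene_mark_enrichment(
    ab_tracks: Sequence[WindowTrack],
    control: WindowTrack,
    genes: Sequence[GeneModel],
    fc_min: float = 2.0,
    pseudo: float = 8.0,
) -> "pd.DataFrame":
    """Per-gene mark enrichment over the MNase control on exon-overlapping
    windows; a gene is 'marked' when enrichment exceeds ``fc_min``."""
    import pandas as pd

    for t in ab_tracks:
        if not t.same_tiling(control):
            raise ValueError("antibody/control tiling mismatch")
    scaled = _scale_tracks(list(ab_tracks) + [control])
    ab_scaled, ctrl_scaled = scaled[:-1], scaled[-1]
    rows = {}
    for g in genes:
        if not g.exons:
            raise ValueError(f"gene {g.gene_id} has no exons")
        ab = np.mean([_exon_overlap_count(t, g) for t in ab_scaled])
        ctrl = _exon_overlap_count(ctrl_scaled, g)
        enr = (ab + pseudo) / (ctrl + pseudo)
        rows[g.gene_id] = enr
    df = pd.DataFrame({"enrichment": pd.Series(rows)})
    df["marked"] = df["enrichment"] > fc_min
    df["log2_enrichment"] = np.log2(df["enrichment"])
    return df


def arm_centre_annotate(
    chrom: str,
    position: int,
    borders: dict[str, tuple[int, ...]] | None = None,
) -> str:
    """Classify a coordinate as chromosome 'arm' or 'centre'.

    Uses the printed ce10 border coordinates by default; chromosomes with
    two borders are arm/centre/arm, chromosome X's single border splits a
    left arm from the rest (treated as centre).
    """
    table = CE10_ARM_BORDERS if borders is None else borders
    if chrom not in table:
        raise KeyError(f"no arm/centre borders for chromosome {chrom!r}")
    b = table[chrom]
    if len(b) == 1:
        return "arm" if position < b[0] else "centre"
    left, right = b
    return "centre" if left <= position <= right else "arm"
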