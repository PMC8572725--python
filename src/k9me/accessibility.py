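"""ATAC-seq post-alignment processing and expression-accessibility grouping.

Covers the Tn5 +4/−5 cut-site correction, differential peak and promoter
accessibility via the exact count test, annotation of peaks to genomic
feature classes (promoter > repeat > exon > intron > intergenic
precedence), selection of intergenic peaks (>1.5 kb from any promoter,
no repeat overlap), and the joint expression/accessibility gene grouping:
Group A (expression up only), Group B (both up), Group C (accessibility
up only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from k9me.expression import (
    CountMatrix,
    DEResult,
    differential_expression,
)
from k9me.genomic_io import GeneModel, Interval
from k9me.motifs import promoter_windows

FEATURE_PRECEDENCE = ("promoter", "repeat", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class CutSite:
    """A Tn5 insertion point after the +4/−5 strand correction."""

    chrom: str
    pos: int
    strand: str


def shift_tn5(
    fragment: Interval, chrom_length: int | None = None
) -> CutSite:
    """Shift a stranded single-end read to its Tn5 cut site.

    Plus strand: start + 4. Minus strand: the read's 5' end is its last
    covered base (end − 1 in half-open coordinates), shifted 5'-ward by
    5, giving end − 6. Positions past the chromosome ends are clipped
    (with a warning).
    """
    if fragment.strand not in ("+", "-"):
        raise ValueError("shift_tn5 requires a stranded fragment")
    if fragment.strand == "+":
        pos = fragment.start + 4
    else:
        pos = fragment.end - 1 - 5
    upper = (chrom_length - 1) if chrom_length is not None else None
    if pos < 0 or (upper is not None and pos > upper):
        warnings.warn(f"cut site clipped for {fragment}", stacklevel=2)
        pos = max(pos, 0)
        if upper is not None:
            pos = min(pos, upper)
    return CutSite(chrom=fragment.chrom, pos=pos, strand=fragment.strand)


def shift_fragments(
    fragments: Sequence[Interval], chrom_lengths: Mapping[str, int] | None = None
) -> list[CutSite]:
    lengths = chrom_lengths or {}
    return [shift_tn5(f, lengths.get(f.chrom)) for f in fragments]


def differential_peaks(
    peaks: CountMatrix,
    contrast: tuple[str, str],
    fdr_max: float = 0.01,
) -> pd.DataFrame:
    """Differential peak accessibility via the exact count test.

    Returns the DE table with boolean ``up`` (FDR < fdr_max and
    log2FC > 0) and ``down`` columns.
    """
    de = differential_expression(peaks, contrast)
    table = de.table.copy()
    table["up"] = (table["fdr"] < fdr_max) & (table["log2fc"] > 0)
    table["down"] = (table["fdr"] < fdr_max) & (table["log2fc"] < 0)
    return table


def _paint_classes(
    chrom_lengths: Mapping[str, int],
    genes: Sequence[GeneModel],
    repeats: Sequence[Interval],
    promoter_up: int,
    promoter_down: int,
) -> dict[str, np.ndarray]:
    """Per-base feature class index under the precedence rule.

    Painted lowest-precedence first so later paints win; class index is
    position in FEATURE_PRECEDENCE.
    """
    idx = {c: i for i, c in enumerate(FEATURE_PRECEDENCE)}
    paint = {
        c: np.full(L, idx["intergenic"], dtype=np.int8)
        for c, L in chrom_lengths.items()
    }
    for g in genes:  # intron: gene span minus exons
        s, e = g.span.start, g.span.end
        paint[g.chrom][s:e] = np.minimum(paint[g.chrom][s:e], idx["intron"])
    for g in genes:
        for s, e in g.exons:
            paint[g.chrom][s:e] = np.minimum(paint[g.chrom][s:e], idx["exon"])
    for r in repeats:
        if r.chrom in paint:
            paint[r.chrom][r.start : r.end] = np.minimum(
                paint[r.chrom][r.start : r.end], idx["repeat"]
            )
    proms = promoter_windows(
        genes, upstream=promoter_up, downstream=promoter_down,
        chrom_lengths=dict(chrom_lengths),
    )
    for iv in proms.values():
        paint[iv.chrom][iv.start : iv.end] = idx["promoter"]
    return paint


def annotate_peak_features(
    peaks: Sequence[Interval],
    genes: Sequence[GeneModel],
    repeats: Sequence[Interval],
    chrom_lengths: Mapping[str, int],
    promoter_up: int = 1_000,
    promoter_down: int = 100,
) -> pd.DataFrame:
    """Assign each peak one feature label with precedence
    promoter > repeat > exon > intron > intergenic (>= 1 bp overlap).

    Also returns per-class genome base fractions so enrichment relative
    to genome-wide occurrence can be computed.
    """
    paint = _paint_classes(chrom_lengths, genes, repeats, promoter_up, promoter_down)
    labels = []
    for p in peaks:
        if p.chrom not in paint:
            labels.append("intergenic")
            continue
        classes = paint[p.chrom][p.start : p.end]
        labels.append(FEATURE_PRECEDENCE[int(classes.min())])
    names = [
        p.label if p.label is not None else f"peak_{i}" for i, p in enumerate(peaks)
    ]
    genome_bases = {c: 0 for c in FEATURE_PRECEDENCE}
    for arr in paint.values():
        binc = np.bincount(arr, minlength=len(FEATURE_PRECEDENCE))
        for i, c in enumerate(FEATURE_PRECEDENCE):
            genome_bases[c] += int(binc[i])
    total = sum(genome_bases.values())
    df = pd.DataFrame({"feature": labels}, index=names)
    df.attrs["genome_fraction"] = {c: genome_bases[c] / total for c in FEATURE_PRECEDENCE}
    return df


def feature_enrichment(
    annotated: pd.DataFrame, selector: pd.Series | None = None
) -> pd.DataFrame:
    """Percentage of (selected) peaks per class relative to genome-wide
    occurrence: (fraction of peaks in class) / (fraction of genome bases
    in class)."""
    sub = annotated if selector is None else annotated[selector.reindex(annotated.index)]
    frac_peaks = sub["feature"].value_counts(normalize=True)
    genome_frac = annotated.attrs["genome_fraction"]
    rows = {}
    for c in FEATURE_PRECEDENCE:
        fp = float(frac_peaks.get(c, 0.0))
        fg = genome_frac.get(c, 0.0)
        rows[c] = {
            "peak_fraction": fp,
            "genome_fraction": fg,
            "relative_enrichment": fp / fg if fg > 0 else np.nan,
        }
    return pd.DataFrame(rows).T


def select_intergenic_peaks(
    peaks: Sequence[Interval],
    promoters: Mapping[str, Interval] | Sequence[Interval],
    repeats: Sequence[Interval],
    min_distance: int = 1_500,
) -> list[Interval]:
    """Peaks more than ``min_distance`` bp from every promoter and with no
    repeat overlap (the study's definition of intergenic enhancer
    candidate peaks)."""
    prom_list = (
        list(promoters.values()) if isinstance(promoters, Mapping) else list(promoters)
    )
    proms_by_chrom: dict[str, list[Interval]] = {}
    for iv in prom_list:
        proms_by_chrom.setdefault(iv.chrom, []).append(iv)
    reps_by_chrom: dict[str, list[Interval]] = {}
    for iv in repeats:
        reps_by_chrom.setdefault(iv.chrom, []).append(iv)

    kept = []
    for p in peaks:
        ok = True
        for prom in proms_by_chrom.get(p.chrom, []):
            d = p.distance(prom)
            if d is not None and d <= min_distance:
                ok = False
                break
        if ok:
            for rep in reps_by_chrom.get(p.chrom, []):
                if p.overlaps(rep):
                    ok = False
                    break
        if ok:
            kept.append(p)
    return kept


def count_cut_sites_in_promoters(
    cut_sites_by_sample: Mapping[str, Sequence[CutSite]],
    promoters: Mapping[str, Interval],
    samples: pd.DataFrame,
) -> CountMatrix:
    """Count shifted Tn5 cut sites per promoter per sample."""
    gene_ids = list(promoters)
    counts = pd.DataFrame(
        0, index=gene_ids, columns=list(cut_sites_by_sample), dtype=np.int64
    )
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gid, iv in promoters.items():
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, gid))
    for c in by_chrom:
        by_chrom[c].sort()
    for sample, sites in cut_sites_by_sample.items():
        for site in sites:
            for s, e, gid in by_chrom.get(site.chrom, []):
                if s > site.pos:
                    break
                if s <= site.pos < e:
                    counts.loc[gid, sample] += 1
    return CountMatrix(counts=counts, samples=samples)


def promoter_accessibility(
    promoter_counts: CountMatrix,
    contrast: tuple[str, str],
    fdr_max: float = 0.01,
) -> pd.DataFrame:
    """Per-gene promoter accessibility DE; ``up`` = FDR < fdr_max and
    log2FC > 0."""
    de = differential_expression(promoter_counts, contrast)
    table = de.table.copy()
    table["up"] = (table["fdr"] < fdr_max) & (table["log2fc"] > 0)
    return table


def classify_groups(
    expression_de: DEResult | pd.DataFrame,
    accessibility_de: pd.DataFrame,
    expr_fdr: float = 0.01,
    expr_log2fc: float = 2.0,
    acc_fdr: float = 0.01,
) -> pd.DataFrame:
    """Joint expression/accessibility gene grouping.

    Group A: expression up (FDR < expr_fdr, log2FC > expr_log2fc) without
    increased accessibility; Group B: both; Group C: accessibility up
    (FDR < acc_fdr, log2FC > 0) without increased expression; 'none'
    otherwise.
    """
    expr = expression_de.table if isinstance(expression_de, DEResult) else expression_de
    if set(expr.index) != set(accessibility_de.index):
        raise ValueError("expression and accessibility tables cover different genes")
    acc = accessibility_de.reindex(expr.index)
    expr_up = (expr["fdr"] < expr_fdr) & (expr["log2fc"] > expr_log2fc)
    acc_up = (acc["fdr"] < acc_fdr) & (acc["log2fc"] > 0)
    group = pd.Series("none", index=expr.index, name="group")
    group[expr_up & ~acc_up] = "A"
    group[expr_up & acc_up] = "B"
    group[~expr_up & acc_up] = "C"
    return pd.DataFrame(
        {"group": group, "expression_up": expr_up, "accessibility_up": acc_up}
    )
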