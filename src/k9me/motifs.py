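"""PWM genome scanning and promoter motif enrichment.

Scanning follows the score-threshold rule used in the study: a window is
a hit when its additive PWM score reaches 10, unless the matrix's
maximum obtainable score is below 10, in which case the maximum is
required (i.e. only perfect matches count). Both strands are scanned and
hits reported in forward-strand coordinates. Windows containing ``N``
never hit.

Enrichment compares per-gene promoter hit rates in a gene set against
the whole annotation, on log2 scale, with the study's calling rule
(log2 enrichment > 0.5 and log2 genome-wide abundance > 8).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from k9me.expression import GeneSet
from k9me.genomic_io import GeneModel, GenomeSequence, Interval, PWMatrix

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
# complement row order: A<->T, C<->G
_COMPLEMENT_ROWS = np.array([3, 2, 1, 0])


@dataclass(frozen=True)
class MotifHit:
    """One PWM match; ``start`` is the forward-strand coordinate of the
    matched window regardless of strand."""

    tf_names: tuple[str, ...]
    chrom: str
    strand: str
    start: int
    score: float

    @property
    def name(self) -> str:
        return "/".join(self.tf_names)


def promoter_windows(
    genes: Sequence[GeneModel],
    upstream: int = 1_500,
    downstream: int = 500,
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, Interval]:
    """Strand-aware promoter intervals around each TSS, clipped to bounds.

    Plus strand: [tss - upstream, tss + downstream); minus strand the
    mirror image. Defaults are the motif-analysis promoter (1,500 bp 5'
    and 500 bp 3' of the TSS); the accessibility promoter uses 1,000/100.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("window extents must be non-negative")
    out = {}
    for g in genes:
        if g.strand == "+":
            start, end = g.tss - upstream, g.tss + downstream
        else:
            start, end = g.tss - downstream, g.tss + upstream
        start = max(0, start)
        if chrom_lengths is not None:
            end = min(end, chrom_lengths[g.chrom])
        if start < end:
            out[g.gene_id] = Interval(
                g.chrom, start, end, strand=g.strand, label=g.gene_id
            )
    return out


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Additive PWM score at every start position; -inf where the window
    contains a non-ACGT base."""
    L = weights.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = weights[safe, np.arange(L)].sum(axis=1)
    scores[~valid] = -np.inf
    return scores


def scan_pwm(
    genome: GenomeSequence,
    pwm: PWMatrix,
    min_score: float = 10.0,
) -> list[MotifHit]:
    """Scan both strands of every chromosome for PWM matches.

    The effective threshold is ``min(min_score, pwm.max_score)``; hits
    require score >= threshold. Minus-strand hits are scored against the
    reverse complement and reported at the forward-strand coordinate of
    the window.
    """
    thresh = min(min_score, pwm.max_score)
    # reverse-complement matrix: complement rows, reverse columns
    rc_weights = pwm.weights[_COMPLEMENT_ROWS][:, ::-1]
    hits: list[MotifHit] = []
    names = tuple(pwm.tf_names)
    for chrom, seq in genome.sequences.items():
        codes = _encode(seq)
        for strand, w in (("+", pwm.weights), ("-", rc_weights)):
            scores = _window_scores(codes, w)
            for pos in np.nonzero(scores >= thresh)[0]:
                hits.append(
                    MotifHit(
                        tf_names=names,
                        chrom=chrom,
                        strand=strand,
                        start=int(pos),
                        score=float(scores[pos]),
                    )
                )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def scan_pwm_set(
    genome: GenomeSequence, pwms: Sequence[PWMatrix], min_score: float = 10.0
) -> dict[str, list[MotifHit]]:
    """Scan every PWM; keyed by motif name (TF names joined with '/')."""
    return {p.name: scan_pwm(genome, p, min_score) for p in pwms}


def promoter_hit_counts(
    hits_by_tf: Mapping[str, Sequence[MotifHit]],
    promoters: Mapping[str, Interval],
    motif_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Per-TF x per-gene motif hit counts.

    A hit is counted for a gene when the matched window overlaps the
    gene's promoter by >= 1 bp; a hit overlapping several promoters
    counts for each. Counting is site-count-weighted (every site counts,
    overlapping sites of one TF included).
    """
    gene_ids = list(promoters)
    table = pd.DataFrame(
        0, index=list(hits_by_tf), columns=gene_ids, dtype=np.int64
    )
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gid, iv in promoters.items():
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, gid))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    for tf, hits in hits_by_tf.items():
        L = motif_lengths[tf]
        for h in hits:
            h_start, h_end = h.start, h.start + L
            for p_start, p_end, gid in by_chrom.get(h.chrom, []):
                if p_start >= h_end:
                    break
                if h_start < p_end and p_start < h_end:
                    table.loc[tf, gid] += 1
    return table


def motif_enrichment(
    counts: pd.DataFrame,
    gene_set: GeneSet | Sequence[str],
    genome_hits: Mapping[str, int],
    enr_min: float = 0.5,
    abund_min: float = 8.0,
    epsilon: float | None = None,
) -> pd.DataFrame:
    """Set-vs-universe promoter motif enrichment, one row per motif.

    rate_set is the mean promoter hit count over set genes, rate_all the
    mean over the whole universe; log2_enrichment = log2((rate_set + eps)
    / (rate_all + eps)) with eps = 1/|universe| by default so zero-rate
    motifs stay finite. log2_abundance = log2(genome-wide hits + 1). A
    motif is called enriched when log2_enrichment > ``enr_min`` and
    log2_abundance > ``abund_min``.
    """
    set_ids = [g for g in counts.columns if g in gene_set] if not isinstance(
        gene_set, (list, tuple)
    ) else [g for g in counts.columns if g in set(gene_set)]
    universe = list(counts.columns)
    if not set_ids:
        raise ValueError("empty gene set (or set disjoint from universe)")
    eps = 1.0 / len(universe) if epsilon is None else epsilon

    rate_set = counts[set_ids].sum(axis=1) / len(set_ids)
    rate_all = counts[universe].sum(axis=1) / len(universe)
    log2_enr = np.log2((rate_set + eps) / (rate_all + eps))
    abundance = pd.Series(
        {tf: genome_hits.get(tf, 0) for tf in counts.index}, dtype=float
    )
    log2_abund = np.log2(abundance + 1)
    out = pd.DataFrame(
        {
            "hits_set": counts[set_ids].sum(axis=1),
            "hits_all": counts[universe].sum(axis=1),
            "hits_genomewide": abundance.astype(np.int64),
            "log2_abundance": log2_abund,
            "log2_enrichment": log2_enr,
        }
    )
    out["enriched"] = (out["log2_enrichment"] > enr_min) & (
        out["log2_abundance"] > abund_min
    )
    return out


def region_hit_counts(
    hits_by_tf: Mapping[str, Sequence[MotifHit]],
    regions: Sequence[Interval],
    motif_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Per-TF x per-region hit counts for arbitrary regions (e.g.
    intergenic accessibility peaks); same overlap rule as promoters."""
    named = {
        (r.label if r.label is not None else f"region_{i}"): r
        for i, r in enumerate(regions)
    }
    return promoter_hit_counts(hits_by_tf, named, motif_lengths)
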