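"""Genome, gene-model, interval and PWM I/O with a single coordinate contract.

All internal coordinates are 0-based, half-open. BED is native; GFF3
(1-based, inclusive) is converted at the boundary. Sequences are
upper-cased on read; ``N`` is permitted but motif scanning treats any
window containing ``N`` as unscorable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from gffutils.feature import feature_from_line


class FormatError(ValueError):
    """Malformed input file or record."""


class BoundsError(ValueError):
    """Coordinates fall outside the chromosome."""


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise BoundsError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in (None, "+", "-"):
            raise FormatError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance(self, other: "Interval") -> int | None:
        """Gap between intervals (0 if overlapping); None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


class GenomeSequence:
    """Chromosome name -> upper-case nucleotide string over {A,C,G,T,N}."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise FormatError("empty genome")
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            if len(seq) == 0:
                raise FormatError(f"zero-length chromosome {name!r}")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise FormatError(f"non-nucleotide characters in {name!r}: {bad}")
            self.sequences[name] = seq

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.sequences.items()}

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeSequence) and self.sequences == other.sequences

    def fetch(self, iv: Interval) -> str:
        if iv.chrom not in self.sequences:
            raise BoundsError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > len(self.sequences[iv.chrom]):
            raise BoundsError(f"interval {iv} beyond chromosome end")
        return self.sequences[iv.chrom][iv.start : iv.end]


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS and sorted disjoint half-open exons."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"unknown strand {self.strand!r}")
        if not self.exons:
            raise FormatError(f"gene {self.gene_id}: no exons")
        prev_end = -1
        for start, end in self.exons:
            if start < 0 or start >= end:
                raise FormatError(f"gene {self.gene_id}: bad exon [{start},{end})")
            if start < prev_end:
                raise FormatError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = end

    @property
    def tss(self) -> int:
        """5'-most position: min start on +, max end on − (half-open excl.)."""
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.exons[0][0], self.exons[-1][1],
                        strand=self.strand, label=self.gene_id)

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class PWMatrix:
    """Position weight matrix: 4 x L real weights in A,C,G,T row order.

    One motif can map to several TFs (e.g. paralogous bHLH pairs), hence
    ``tf_names`` is a list. ``max_score`` is the sum over columns of
    column maxima — the best score any sequence can reach.
    """

    tf_names: list[str]
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != 4:
            raise FormatError(
                f"PWM for {self.tf_names}: expected 4 x L matrix, "
                f"got shape {self.weights.shape}"
            )
        if self.weights.shape[1] < 1:
            raise FormatError(f"PWM for {self.tf_names}: zero-length motif")
        if not self.tf_names:
            raise FormatError("PWM with no TF names")
        if np.all(self.weights == 0):
            warnings.warn(f"all-zero PWM for {self.tf_names}", stacklevel=2)

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.weights.argmax(axis=0))

    @property
    def name(self) -> str:
        return "/".join(self.tf_names)


# --------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA genome; sequences are upper-cased, duplicates rejected."""
    path = Path(path)
    records = {}
    with open(path) as fh:
        first = fh.read(1)
        if not first:
            raise FormatError(f"{path}: empty FASTA")
        if first != ">":
            raise FormatError(f"{path}: malformed header (expected '>')")
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return GenomeSequence(records)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# gene models


def read_gene_models(
    path: str | Path,
    dialect: str = "gff3",
    chrom_lengths: dict[str, int] | None = None,
) -> list[GeneModel]:
    """Read gene models from GFF3 (1-based inclusive) or TSV (0-based half-open).

    The TSV dialect has columns gene_id, chrom, strand, exons where exons
    is ``start-end`` pairs joined by ``,`` in internal coordinates.
    GFF3 exon features carry the gene id in the ``Parent`` (or ``ID``)
    attribute and are converted to 0-based half-open at the boundary.
    """
    path = Path(path)
    exons_by_gene: dict[str, list[tuple[str, str, int, int]]] = {}
    order: list[str] = []

    if dialect == "gff3":
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                feat = feature_from_line(line)
                if feat.featuretype != "exon":
                    continue
                parents = feat.attributes.get("Parent") or feat.attributes.get("ID")
                if not parents:
                    raise FormatError(f"{path}: exon without Parent/ID: {line}")
                gid = parents[0]
                if feat.strand not in ("+", "-"):
                    raise FormatError(f"{path}: unknown strand {feat.strand!r}")
                # GFF3 is 1-based inclusive -> 0-based half-open
                exons_by_gene.setdefault(gid, []).append(
                    (feat.seqid, feat.strand, feat.start - 1, feat.end)
                )
                if gid not in order:
                    order.append(gid)
    elif dialect == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for col in ("gene_id", "chrom", "strand", "exons"):
                if col not in idx:
                    raise FormatError(f"{path}: missing column {col!r}")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                gid = parts[idx["gene_id"]]
                chrom = parts[idx["chrom"]]
                strand = parts[idx["strand"]]
                if strand not in ("+", "-"):
                    raise FormatError(f"{path}: unknown strand {strand!r}")
                for token in parts[idx["exons"]].split(","):
                    s, e = token.split("-")
                    exons_by_gene.setdefault(gid, []).append(
                        (chrom, strand, int(s), int(e))
                    )
                if gid not in order:
                    order.append(gid)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    genes = []
    for gid in order:
        recs = exons_by_gene[gid]
        chroms = {r[0] for r in recs}
        strands = {r[1] for r in recs}
        if len(chroms) != 1 or len(strands) != 1:
            raise FormatError(f"gene {gid}: exons on multiple chromosomes/strands")
        chrom, strand = recs[0][0], recs[0][1]
        exons = tuple(sorted((s, e) for _, _, s, e in recs))
        if chrom_lengths is not None:
            L = chrom_lengths.get(chrom)
            if L is None:
                raise BoundsError(f"gene {gid}: unknown chromosome {chrom!r}")
            if exons[-1][1] > L:
                raise BoundsError(f"gene {gid}: exon beyond chromosome end")
        genes.append(GeneModel(gid, chrom, strand, exons))
    if len({g.gene_id for g in genes}) != len(genes):
        raise FormatError("duplicate gene ids")
    return genes


def write_gene_models_tsv(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\texons\n")
        for g in genes:
            exon_str = ",".join(f"{s}-{e}" for s, e in g.exons)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{exon_str}\n")


def write_gene_models_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write exon features in GFF3 (1-based inclusive) coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tk9me\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={g.gene_id}\n"
                )


# --------------------------------------------------------------------------
# BED intervals


def read_intervals(path: str | Path) -> list[Interval]:
    """Read a BED3+ file (0-based half-open; cols 4/6 become label/strand)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: BED line with <3 fields: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 and parts[3] != "." else None
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else None
            out.append(Interval(chrom, start, end, strand=strand, label=label))
    return out


def write_intervals(
    intervals: Iterable[Interval],
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write intervals as BED (BED6 when strand/label/score present)."""
    intervals = list(intervals)
    if chrom_lengths is not None:
        for iv in intervals:
            L = chrom_lengths.get(iv.chrom)
            if L is None or iv.end > L:
                raise BoundsError(f"interval {iv} out of bounds")
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            extended = (
                iv.label is not None
                or iv.strand is not None
                or scores is not None
            )
            if extended:
                fields.append(iv.label if iv.label is not None else ".")
                fields.append(f"{scores[i]:g}" if scores is not None else "0")
                fields.append(iv.strand if iv.strand is not None else ".")
            fh.write("\t".join(fields) + "\n")


# --------------------------------------------------------------------------
# PWMs


def read_pwm_set(path: str | Path) -> list[PWMatrix]:
    """Read a PWM library: blocks of 4 tab-separated rows labelled A,C,G,T.

    Each block starts with a ``>name`` line; multiple TF names for one
    motif are joined with ``/``.
    """
    path = Path(path)
    pwms: list[PWMatrix] = []
    name: str | None = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal rows, name
        if name is None:
            return
        if set(rows) != {"A", "C", "G", "T"}:
            raise FormatError(
                f"{path}: motif {name!r} must have exactly rows A,C,G,T "
                f"(got {sorted(rows)})"
            )
        w = np.array([rows[b] for b in "ACGT"])
        pwms.append(PWMatrix(tf_names=name.split("/"), weights=w))
        rows = {}

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip()
                if not name:
                    raise FormatError(f"{path}: motif with empty name")
            else:
                parts = line.split("\t")
                base = parts[0]
                if name is None:
                    raise FormatError(f"{path}: matrix row before any '>' header")
                if base in rows:
                    raise FormatError(f"{path}: duplicate row {base!r} in {name!r}")
                rows[base] = [float(x) for x in parts[1:]]
    flush()
    if not pwms:
        raise FormatError(f"{path}: no PWMs found")
    return pwms


def write_pwm_set(pwms: Sequence[PWMatrix], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.name}\n")
            for i, base in enumerate("ACGT"):
                vals = "\t".join(f"{v:g}" for v in p.weights[i])
                fh.write(f"{base}\t{vals}\n")
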