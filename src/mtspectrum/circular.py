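"""Circular-coordinate arithmetic and the doubled mitochondrial reference.

Mitochondrial DNA is a circular molecule (~16.3 kb in mouse), but read
aligners and variant callers work on linear references.  Deletions whose
junction crosses the arbitrary linearization origin are invisible on a
single-copy reference; the standard workaround is to align against two
tandem copies of the sequence (the "doubled" reference, dMT), so that any
junction on the circle appears as a contiguous interval somewhere on the
2L-long linear sequence.  This module provides the genome container, the
doubled-reference view, modular coordinate arithmetic, origin-wrapping
window extraction, and gene assignment.

Conventions
-----------
Internal coordinates are 0-based, half-open, on the forward strand of the
L-long circle.  Human-readable table output elsewhere in the package uses
1-based closed positions.  Origin-spanning gene features are encoded as a
single record with ``start > end``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

_VALID_BASES = frozenset("ACGTN")
_GENE_CATEGORIES = ("protein", "tRNA", "rRNA", "NCR")


class InvalidGenomeError(ValueError):
    """Raised when a genome or annotation violates its invariants."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated feature on the circle.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive; ``end < start``
    encodes a feature spanning the origin.  ``category`` is one of
    ``protein``, ``tRNA``, ``rRNA``, ``NCR``.
    """

    gene_id: str
    start: int
    end: int
    category: str = "protein"

    def length(self, L: int) -> int:
        return (self.end - self.start) % L

    def contains(self, p: int, L: int) -> bool:
        if self.start <= self.end:
            return self.start <= p < self.end
        return p >= self.start or p < self.end


@dataclass(frozen=True)
class CircularGenome:
    """A circular DNA sequence with optional gene annotation."""

    name: str
    sequence: str
    genes: tuple[GeneAnnotation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidGenomeError("empty genome sequence")
        if not _VALID_BASES.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - _VALID_BASES)
            raise InvalidGenomeError(f"invalid bases in sequence: {bad}")
        object.__setattr__(self, "genes", tuple(self.genes))
        L = len(self.sequence)
        for gene in self.genes:
            if not (0 <= gene.start < L and 0 <= gene.end <= L):
                raise InvalidGenomeError(
                    f"gene {gene.gene_id} interval ({gene.start}, {gene.end}) "
                    f"outside [0, {L})"
                )
            if gene.length(L) == 0:
                raise InvalidGenomeError(f"gene {gene.gene_id} has zero length")
            if gene.category not in _GENE_CATEGORIES:
                raise InvalidGenomeError(
                    f"gene {gene.gene_id}: unknown category {gene.category!r}"
                )

    @property
    def L(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DoubledReference:
    """Two tandem copies of a circular genome, for alignment."""

    source: CircularGenome
    sequence: str

    @property
    def name(self) -> str:
        return f"{self.source.name}_dMT"


def build_doubled_reference(g: CircularGenome) -> DoubledReference:
    """Concatenate the genome with itself to form the 2L alignment target."""
    return DoubledReference(source=g, sequence=g.sequence + g.sequence)


def normalize_position(p: int, L: int) -> int:
    """Map a position on the doubled reference back onto the circle.

    Accepts ``0 <= p < 2L`` and returns ``p mod L``.
    """
    if not 0 <= p < 2 * L:
        raise ValueError(f"position {p} outside doubled reference [0, {2 * L})")
    return p % L


def circular_distance(a: int, b: int, L: int) -> int:
    """Shortest arc length between two positions on the circle."""
    if not (0 <= a < L and 0 <= b < L):
        raise ValueError(f"positions ({a}, {b}) outside [0, {L})")
    d = (a - b) % L
    return min(d, L - d)


def extract_window(g: CircularGenome, center: int, flank: int) -> str:
    """The 2*flank-base window around a junction, wrapping the origin.

    Returns ``flank`` bases ending at ``center - 1`` followed by ``flank``
    bases starting at ``center``.  With ``center`` interpreted as a
    breakpoint (first deleted / first retained base), this is the sequence
    neighbourhood the breakpoint-identity analysis aligns.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    L = g.L
    if 2 * flank > L:
        raise ValueError(f"window of 2*{flank} bases exceeds genome length {L}")
    c = center % L
    doubled = g.sequence + g.sequence
    start = (c - flank) % L
    return doubled[start : start + 2 * flank]


def window_has_ambiguous(window: str) -> bool:
    """True if a window contains N; such windows are skipped by scoring."""
    return "N" in window


def assign_gene(g: CircularGenome, p: int) -> str:
    """Gene id whose interval contains ``p``, or ``"intergenic"``.

    Overlapping annotations are broken deterministically: first by start
    coordinate, then lexicographically by gene id.
    """
    if not 0 <= p < g.L:
        raise ValueError(f"position {p} outside [0, {g.L})")
    hits = [gene for gene in g.genes if gene.contains(p, g.L)]
    if not hits:
        return "intergenic"
    hits.sort(key=lambda gene: (gene.start, gene.gene_id))
    return hits[0].gene_id


def rotate(g: CircularGenome, r: int) -> CircularGenome:
    """Rotate the linearization origin by ``r`` bases.

    Position ``p`` on the original genome corresponds to ``(p - r) mod L``
    on the rotated one.  Used by invariance tests: all circular statistics
    are unchanged under a joint rotation of genome and coordinates.
    """
    L = g.L
    r %= L
    seq = g.sequence[r:] + g.sequence[:r]
    genes = tuple(
        replace(gene, start=(gene.start - r) % L, end=(gene.end - r) % L or L)
        for gene in g.genes
    )
    return CircularGenome(name=g.name, sequence=seq, genes=genes)


# ---------------------------------------------------------------------------
# FASTA / BED I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a (multi-)FASTA into an ordered dict of name -> sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def genome_from_fasta(path, name: str | None = None,
                      genes: tuple[GeneAnnotation, ...] = ()) -> CircularGenome:
    records = read_fasta(path)
    if not records:
        raise InvalidGenomeError(f"no FASTA records in {path}")
    if name is None:
        name = next(iter(records))
    return CircularGenome(name=name, sequence=records[name], genes=tuple(genes))


def write_doubled_fasta(path, d: DoubledReference) -> None:
    write_fasta(path, {d.name: d.sequence})


def read_bed_genes(path, L: int) -> tuple[GeneAnnotation, ...]:
    """Read gene annotation from BED (0-based half-open).

    Columns: chrom, start, end, name, and an optional category tag in
    column 5 (score slot) or appended to the name as ``name|category``.
    Features whose end exceeds ``L`` are interpreted as origin-spanning and
    re-encoded as ``start > end``.
    """
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = re.split(r"\s+", line)
            if len(parts) < 4:
                raise InvalidGenomeError(f"BED line has <4 columns: {line!r}")
            start, end, name = int(parts[1]), int(parts[2]), parts[3]
            category = "protein"
            if "|" in name:
                name, category = name.rsplit("|", 1)
            elif len(parts) >= 5 and parts[4] in _GENE_CATEGORIES:
                category = parts[4]
            if end > L:  # wraps the origin
                start, end = start % L, end % L
            genes.append(GeneAnnotation(name, start, end, category))
    return tuple(genes)


def write_bed_genes(path, g: CircularGenome) -> None:
    with open(path, "w") as fh:
        for gene in g.genes:
            end = gene.end if gene.end > gene.start else gene.end + g.L
            fh.write(f"{g.name}\t{gene.start}\t{end}\t{gene.gene_id}\t{gene.category}\n")
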