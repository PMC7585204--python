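"""Synthetic circular genomes, planted variants, reads, and cohorts.

Everything downstream of the sequencer is testable without real data: this
module generates (a) random circular genomes carrying planted direct
repeats; (b) paired-end alignments against the doubled reference in which
planted SNVs, deletions, and very-long-range deletions (VLRDs, i.e.
candidate multimers) appear at specified heteroplasmy fractions; and (c)
multi-sample cohorts with a planted age x genotype x brain-region effect
structure mirroring the ageing study design the analysis layer targets.

The read model is deliberately clean: uniform fragment starts on the
circle, constant base quality (Q30), and no sequencing error by default
(an optional uniform substitution rate exists to exercise the filters).
Each sequenced fragment is drawn from a molecule that carries each planted
variant independently with probability equal to its allele fraction;
fraction 1.0 therefore means deterministic membership.  Reads crossing a
deletion junction are emitted with a ``D`` CIGAR operation; mate pairs
whose reference span exceeds ``proper_pair_limit`` lose the proper-pair
flag, which is what the discordant-read extraction (flag mask 1294)
selects.

All outputs are a pure function of the configuration and its seed.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .circular import CircularGenome, GeneAnnotation

logger = logging.getLogger(__name__)

DEFAULT_REGIONS = ("COR", "CP", "DR", "NAc", "PVT", "SN")
DEFAULT_AGES = (10, 50, 80)
VLRD_BOUNDARY = 15000

PHRED_DEFAULT = 30


class ConfigError(ValueError):
    """Raised for infeasible or inconsistent simulation plans."""


# ---------------------------------------------------------------------------
# Plans and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatPlan:
    """Plant two copies of a random ``length``-mer at ``pos_a``/``pos_b``
    differing at exactly ``mismatches`` positions."""

    length: int
    mismatches: int
    pos_a: int
    pos_b: int


@dataclass(frozen=True)
class SnvPlan:
    pos: int
    alt: str
    fraction: float = 1.0


@dataclass(frozen=True)
class DeletionPlan:
    """A deletion of ``length`` bases starting at ``start`` (first deleted
    base); ``start + length`` may exceed L (origin-spanning)."""

    start: int
    length: int
    fraction: float = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    L: int = 16300
    n_genes: int = 15
    repeat_plan: tuple[RepeatPlan, ...] = ()
    snv_plan: tuple[SnvPlan, ...] = ()
    deletion_plan: tuple[DeletionPlan, ...] = ()
    vlrd_plan: tuple[DeletionPlan, ...] = ()
    read_length: int = 150
    depth: float = 200.0
    insert_size: int = 300
    error_rate: float = 0.0
    proper_pair_limit: int = 2000
    copy_choice: str = "random"  # "random" | "first": dMT copy for placement

    def __post_init__(self) -> None:
        if self.L < 100:
            raise ConfigError("genome length must be >= 100")
        if self.read_length < 30 or self.insert_size < self.read_length:
            raise ConfigError("need insert_size >= read_length >= 30")
        for p in self.snv_plan:
            if not 0 <= p.pos < self.L:
                raise ConfigError(f"SNV position {p.pos} outside [0, {self.L})")
            if not 0.0 < p.fraction <= 1.0:
                raise ConfigError(f"allele fraction {p.fraction} outside (0, 1]")
            if p.alt not in "ACGT":
                raise ConfigError(f"invalid alt base {p.alt!r}")
        for p in (*self.deletion_plan, *self.vlrd_plan):
            if not 0 <= p.start < self.L:
                raise ConfigError(f"deletion start {p.start} outside [0, {self.L})")
            if not 1 <= p.length <= self.L - 1:
                raise ConfigError(f"deletion length {p.length} infeasible on L={self.L}")
            if not 0.0 < p.fraction <= 1.0:
                raise ConfigError(f"allele fraction {p.fraction} outside (0, 1]")
        for p in self.vlrd_plan:
            if p.length <= VLRD_BOUNDARY:
                raise ConfigError(
                    f"vlrd_plan length {p.length} must exceed {VLRD_BOUNDARY}"
                )
        if self.copy_choice not in ("random", "first"):
            raise ConfigError(f"unknown copy_choice {self.copy_choice!r}")
        if not 0.0 <= self.error_rate < 0.5:
            raise ConfigError("error_rate must be in [0, 0.5)")

    @property
    def all_deletions(self) -> tuple[DeletionPlan, ...]:
        return (*self.deletion_plan, *self.vlrd_plan)


def random_deletion_lengths(n: int, rng: np.random.Generator) -> np.ndarray:
    """Bimodal deletion-length mixture: half short (<100 bp, uniform on
    [1, 99]), half long (uniform on [1000, 15000])."""
    short = rng.random(n) < 0.5
    lengths = np.where(
        short,
        rng.integers(1, 100, size=n),
        rng.integers(1000, 15001, size=n),
    )
    return lengths


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def default_gene_annotation(L: int, n_genes: int) -> tuple[GeneAnnotation, ...]:
    """Tile the circle with ``n_genes`` features plus a terminal non-coding
    control region, loosely mimicking the dense single-strand gene layout
    of vertebrate mtDNA (protein/tRNA/rRNA categories cycled)."""
    if n_genes <= 0:
        return ()
    ncr_len = max(L // 16, 1)
    coding = L - ncr_len
    bounds = np.linspace(0, coding, n_genes + 1).astype(int)
    cats = ("rRNA", "rRNA") + ("protein", "protein", "tRNA") * n_genes
    genes = []
    for i in range(n_genes):
        if bounds[i + 1] <= bounds[i]:
            continue
        genes.append(
            GeneAnnotation(f"mt-G{i + 1:02d}", int(bounds[i]), int(bounds[i + 1]),
                           cats[i])
        )
    genes.append(GeneAnnotation("NCR", coding, L, "NCR"))
    return tuple(genes)


def generate_genome(cfg: SimulationConfig):
    """Random circular genome with planted approximate direct repeats.

    Returns ``(genome, planted_repeats)`` where the catalogue entries are
    ``(pos_a, pos_b, length, mismatches)`` tuples matching the plan.
    """
    rng = np.random.default_rng(cfg.seed)
    seq = rng.choice(np.frombuffer(b"ACGT", np.uint8), size=cfg.L)

    occupied: list[tuple[int, int]] = []
    planted = []
    for plan in cfg.repeat_plan:
        if plan.length < 8:
            raise ConfigError("planted repeats must be >= 8 bp")
        if plan.mismatches > plan.length:
            raise ConfigError("more planned mismatches than repeat length")
        for pos in (plan.pos_a, plan.pos_b):
            span = (pos, pos + plan.length)
            for a, b in occupied:
                if span[0] < b and a < span[1]:
                    raise ConfigError(
                        f"repeat copies overlap at [{span[0]}, {span[1]})"
                    )
            if span[1] > cfg.L:
                raise ConfigError("planted repeat copy runs past the origin")
            occupied.append(span)
        copy = rng.choice(np.frombuffer(b"ACGT", np.uint8), size=plan.length)
        other = copy.copy()
        sites = rng.choice(plan.length, size=plan.mismatches, replace=False)
        for s in sites:
            choices = [b for b in b"ACGT" if b != other[s]]
            other[s] = rng.choice(choices)
        seq[plan.pos_a : plan.pos_a + plan.length] = copy
        seq[plan.pos_b : plan.pos_b + plan.length] = other
        planted.append((plan.pos_a, plan.pos_b, plan.length, plan.mismatches))

    genome = CircularGenome(
        name=f"synthMT_L{cfg.L}_s{cfg.seed}",
        sequence=seq.tobytes().decode(),
        genes=default_gene_annotation(cfg.L, cfg.n_genes),
    )
    return genome, planted


# ---------------------------------------------------------------------------
# Alignment records
# ---------------------------------------------------------------------------

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_DUP = 0x400
FLAG_SUPPLEMENTARY = 0x800


@dataclass
class AlignmentRecord:
    """One mapped read on the doubled reference.

    ``cigar`` is a tuple of ``(op, length)`` with op in ``MIDNSHP=X``;
    ``qual`` is a tuple of phred scores, one per query base.
    """

    read_id: str
    flags: int
    pos: int
    cigar: tuple[tuple[str, int], ...]
    seq: str
    qual: tuple[int, ...]
    mapq: int = 60
    mate_pos: int = -1
    tlen: int = 0

    @property
    def is_paired(self) -> bool:
        return bool(self.flags & FLAG_PAIRED)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flags & FLAG_UNMAPPED)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flags & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flags & FLAG_SUPPLEMENTARY)

    @property
    def is_read2(self) -> bool:
        return bool(self.flags & FLAG_READ2)

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS=X")

    @property
    def reference_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MDN=X")

    def shifted(self, delta: int) -> "AlignmentRecord":
        rec = replace(self, pos=self.pos + delta)
        if rec.mate_pos >= 0:
            rec.mate_pos += delta
        return rec


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthVariant:
    kind: str  # SNV | DEL | VLRD
    pos5: int
    pos3: int | None
    length: int | None
    ref: str | None
    alt: str | None
    fraction: float


@dataclass
class TruthTable:
    """Ground truth for one simulated sample."""

    sample_id: str
    variants: tuple[TruthVariant, ...]

    @property
    def snvs(self):
        return tuple(v for v in self.variants if v.kind == "SNV")

    @property
    def deletions(self):
        return tuple(v for v in self.variants if v.kind == "DEL")

    @property
    def vlrds(self):
        return tuple(v for v in self.variants if v.kind == "VLRD")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": self.sample_id,
                "kind": v.kind,
                "pos5_1based": v.pos5 + 1,
                "pos3_1based": (v.pos3 + 1) if v.pos3 is not None else "",
                "length": v.length if v.length is not None else "",
                "ref": v.ref or "",
                "alt": v.alt or "",
                "fraction": v.fraction,
            }
            for v in self.variants
        ]
        return pd.DataFrame(rows)


def left_align_deletion(seq: str, start: int, length: int) -> int:
    """Shift a deletion left while the junction is ambiguous.

    The deletion removes ``[start, start+length)`` on the circle; it can be
    shifted one base left whenever the base entering the gap on the right
    equals the base leaving it on the left, i.e. when
    ``seq[(start-1) % L] == seq[(start+length-1) % L]``.  Returns the
    canonical (leftmost) start.  Bounded by one full turn.
    """
    L = len(seq)
    s = start % L
    for _ in range(L):
        if seq[(s - 1) % L] == seq[(s + length - 1) % L]:
            s = (s - 1) % L
        else:
            break
    return s


def _canonical_deletions(seq: str, plans) -> list[DeletionPlan]:
    canon = []
    for p in plans:
        s = left_align_deletion(seq, p.start, p.length)
        canon.append(DeletionPlan(start=s, length=p.length, fraction=p.fraction))
    return canon


def _overlap(L: int, d1: DeletionPlan, d2: DeletionPlan) -> bool:
    a1, b1 = d1.start, d1.start + d1.length  # may extend past L
    a2, b2 = d2.start, d2.start + d2.length
    return any(a1 < b2 + s and a2 + s < b1 for s in (-L, 0, L))


def _check_disjoint(L: int, dels: list[DeletionPlan]) -> None:
    """Overlapping planted deletions are allowed (different molecules can
    carry different rearrangements) unless both are certain (fraction
    1.0), which no molecule could satisfy."""
    for i, d1 in enumerate(dels):
        for d2 in dels[i + 1 :]:
            if _overlap(L, d1, d2) and d1.fraction == d2.fraction == 1.0:
                raise ConfigError(
                    "two fraction-1.0 planted deletions overlap; no single "
                    "molecule can carry both"
                )


def _resolve_conflicts(L: int, carried: list[DeletionPlan]) -> list[DeletionPlan]:
    """Per-molecule: keep each drawn deletion only if it does not overlap
    an already-kept one (plan order).  Overlap therefore slightly reduces
    the effective fraction of later-listed deletions."""
    kept: list[DeletionPlan] = []
    for d in carried:
        if not any(_overlap(L, d, k) for k in kept):
            kept.append(d)
    return kept


def _truth_from_config(g: CircularGenome, cfg: SimulationConfig,
                       sample_id: str) -> TruthTable:
    L = g.L
    variants = []
    for p in cfg.snv_plan:
        variants.append(
            TruthVariant("SNV", p.pos, None, None, g.sequence[p.pos], p.alt,
                         p.fraction)
        )
    for p in _canonical_deletions(g.sequence, cfg.all_deletions):
        kind = "VLRD" if p.length > VLRD_BOUNDARY else "DEL"
        variants.append(
            TruthVariant(kind, p.start, (p.start + p.length) % L, p.length,
                         None, None, p.fraction)
        )
    return TruthTable(sample_id=sample_id, variants=tuple(variants))


def _advance(pos: int, n: int, dels: list[DeletionPlan], L: int) -> tuple[int, int]:
    """Walk ``n`` molecule bases forward from reference position ``pos``
    on a molecule carrying ``dels``; returns (ref_pos mod L, unwrapped ref
    distance travelled)."""
    travelled = 0
    p = pos % L
    remaining = n
    while remaining > 0:
        gap = None
        for d in dels:
            delta = (d.start - p) % L
            if gap is None or delta < gap:
                gap = delta
        if gap is None or gap >= remaining:
            p = (p + remaining) % L
            travelled += remaining
            remaining = 0
        else:
            p = (p + gap) % L
            travelled += gap
            remaining -= gap
            # jump the junction
            for d in dels:
                if d.start == p:
                    p = (p + d.length) % L
                    travelled += d.length
                    break
    return p, travelled


def _read_blocks(start: int, read_len: int, dels: list[DeletionPlan],
                 L: int) -> list[tuple[int, int, int]]:
    """M-blocks for a read of ``read_len`` molecule bases starting at
    reference position ``start``: list of (ref_start mod L, length,
    unwrapped_offset_from_read_start)."""
    blocks = []
    p = start % L
    off = 0  # unwrapped reference offset from read start
    remaining = read_len
    while remaining > 0:
        gap = None
        hit = None
        for d in dels:
            delta = (d.start - p) % L
            if gap is None or delta < gap:
                gap, hit = delta, d
        if gap is None or gap >= remaining:
            blocks.append((p, remaining, off))
            remaining = 0
        else:
            if gap > 0:
                blocks.append((p, gap, off))
            p = (p + gap) % L
            off += gap
            remaining -= gap
            p = (p + hit.length) % L
            off += hit.length
    return blocks


def simulate_alignments(g: CircularGenome, cfg: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        sample_id: str = "sample"):
    """Paired 150-bp reads on the doubled reference with planted variants.

    Returns ``(records, truth)``.  Fragment starts are uniform on the
    circle; each fragment's molecule carries every planted variant
    independently with probability equal to its allele fraction.  Deletion
    junctions inside a read become ``D`` CIGAR operations; junctions
    between the mates stretch the pair span, and pairs spanning more than
    ``cfg.proper_pair_limit`` reference bases lose the proper-pair flag
    (the discordant-pair signature).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    L = g.L
    if cfg.depth * L / cfg.read_length < 50:
        raise ConfigError("depth too low: need depth * L / read_length >= 50")

    dels_canon = _canonical_deletions(g.sequence, cfg.all_deletions)
    _check_disjoint(L, dels_canon)
    snvs = list(cfg.snv_plan)
    doubled = g.sequence + g.sequence
    snv_at = {p.pos: p for p in snvs}

    n_frag = int(round(cfg.depth * L / (2 * cfg.read_length)))
    records: list[AlignmentRecord] = []
    qual = tuple([PHRED_DEFAULT] * cfg.read_length)

    for i in range(n_frag):
        carried_dels = _resolve_conflicts(
            L, [d for d in dels_canon if rng.random() < d.fraction]
        )
        carried_snvs = {p.pos for p in snvs if rng.random() < p.fraction}

        # fragment start: uniform on the circle, nudged out of deleted spans
        s0 = int(rng.integers(0, L))
        for d in carried_dels:
            if (s0 - d.start) % L < d.length:
                s0 = (d.start + d.length) % L
                break

        reads = []
        ok = True
        mate_start, _ = _advance(s0, cfg.insert_size - cfg.read_length,
                                 carried_dels, L)
        for rstart in (s0, mate_start):
            blocks = _read_blocks(rstart, cfg.read_length, carried_dels, L)
            # the alignment starts at the first aligned block; a read whose
            # sampled start sits exactly on a junction begins after the jump
            b0 = blocks[0][2]
            aln_start = (rstart + b0) % L
            span = blocks[-1][2] + blocks[-1][1] - b0  # aligned ref span
            if aln_start + span > 2 * L:
                ok = False
                break
            reads.append((aln_start, blocks, b0, span))
        if not ok:
            continue  # not representable on the 2L reference; rare corner

        # choose dMT copy for the whole pair
        offset = 0
        hi = max(aln_start + span for aln_start, _, _, span in reads)
        if cfg.copy_choice == "random" and hi + L <= 2 * L and rng.random() < 0.5:
            offset = L

        segs = []
        for aln_start, blocks, b0, span in reads:
            cigar = []
            seq_parts = []
            prev_end = None
            base = aln_start - b0  # so base + boff tracks the alignment
            for bpos, blen, boff in blocks:
                if prev_end is not None and boff > prev_end:
                    cigar.append(("D", boff - prev_end))
                cigar.append(("M", blen))
                prev_end = boff + blen
                frag = list(doubled[base + boff : base + boff + blen])
                for k in range(blen):
                    ref_p = (bpos + k) % L
                    if ref_p in carried_snvs:
                        frag[k] = snv_at[ref_p].alt
                seq_parts.append("".join(frag))
            seq = "".join(seq_parts)
            if cfg.error_rate > 0:
                arr = list(seq)
                errs = np.flatnonzero(rng.random(len(arr)) < cfg.error_rate)
                for e in errs:
                    arr[e] = "ACGT"[int(rng.integers(0, 4))]
                seq = "".join(arr)
            # merge adjacent M ops
            merged = []
            for op, n in cigar:
                if merged and merged[-1][0] == op:
                    merged[-1] = (op, merged[-1][1] + n)
                else:
                    merged.append((op, n))
            segs.append((aln_start + offset, tuple(merged), seq, span))

        pair_span = max(p + s for p, _, _, s in segs) - min(p for p, _, _, s in segs)
        proper = pair_span <= cfg.proper_pair_limit
        base_flags = FLAG_PAIRED | (FLAG_PROPER if proper else 0)
        f1 = base_flags | FLAG_READ1 | FLAG_MATE_REVERSE
        f2 = base_flags | FLAG_READ2 | FLAG_REVERSE
        name = f"{sample_id}:frag{i:07d}"
        p1, c1, s1, sp1 = segs[0]
        p2, c2, s2, sp2 = segs[1]
        records.append(AlignmentRecord(name, f1, p1, c1, s1, qual,
                                       mate_pos=p2, tlen=pair_span))
        records.append(AlignmentRecord(name, f2, p2, c2, s2, qual,
                                       mate_pos=p1, tlen=-pair_span))

    records.sort(key=lambda r: (r.pos, r.read_id))
    truth = _truth_from_config(g, cfg, sample_id)
    return records, truth


# ---------------------------------------------------------------------------
# SAM I/O (plain text via pysam)
# ---------------------------------------------------------------------------

def sam_header(g: CircularGenome) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": f"{g.name}_dMT", "LN": 2 * g.L}],
    }


def write_sam(path, records, g: CircularGenome) -> None:
    import pysam

    header = pysam.AlignmentHeader.from_dict(sam_header(g))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(header)
            a.query_name = rec.read_id
            a.flag = rec.flags
            a.reference_id = 0
            a.reference_start = rec.pos
            a.mapping_quality = rec.mapq
            a.cigarstring = "".join(f"{n}{op}" for op, n in rec.cigar)
            a.query_sequence = rec.seq
            a.query_qualities = list(rec.qual)
            if rec.mate_pos >= 0:
                a.next_reference_id = 0
                a.next_reference_start = rec.mate_pos
            a.template_length = rec.tlen
            out.write(a)


def read_sam(path) -> list[AlignmentRecord]:
    import pysam

    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            cigar = tuple(
                ("MIDNSHP=XB"[op], n) for op, n in (a.cigartuples or ())
            )
            records.append(
                AlignmentRecord(
                    read_id=a.query_name,
                    flags=a.flag,
                    pos=a.reference_start,
                    cigar=cigar,
                    seq=a.query_sequence or "",
                    qual=tuple(a.query_qualities or ()),
                    mapq=a.mapping_quality,
                    mate_pos=a.next_reference_start if a.is_paired else -1,
                    tlen=a.template_length,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDesign:
    """Planted effect structure for a multi-sample ageing cohort.

    Expected per-sample variant count =
    ``baseline * age_multiplier * genotype_region_multiplier *
    exp(animal_effect)`` with Poisson sampling.  The genotype x region
    multiplier applies to mutant samples from ``affected_regions`` at ages
    >= ``effect_onset_age`` (the proof-reading-deficient genotype has no
    effect in young animals).
    """

    genotypes: tuple[str, ...] = ("WT", "mutant")
    regions: tuple[str, ...] = DEFAULT_REGIONS
    ages: tuple[int, ...] = DEFAULT_AGES
    animals_per_cell: int = 5
    baseline_snv: float = 20.0
    baseline_del: float = 8.0
    age_multipliers_snv: tuple[tuple[int, float], ...] = ((10, 1.0), (50, 10.0), (80, 10.0))
    age_multipliers_del: tuple[tuple[int, float], ...] = ((10, 1.0), (50, 2.75), (80, 2.75))
    genotype_region_multiplier: float = 3.0
    affected_regions: tuple[str, ...] = ("COR", "NAc", "PVT")
    effect_onset_age: int = 50
    animal_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.animals_per_cell < 2:
            raise ConfigError("need >= 2 animals per cell for ANOVA testability")
        for _, m in (*self.age_multipliers_snv, *self.age_multipliers_del):
            if m <= 0:
                raise ConfigError("multipliers must be > 0")
        if self.genotype_region_multiplier <= 0:
            raise ConfigError("multipliers must be > 0")


def simulate_cohort(design: CohortDesign, seed: int,
                    emit_reads: bool = False, out_dir=None,
                    base_config: SimulationConfig | None = None) -> pd.DataFrame:
    """Per-sample planted variant counts for the full factorial design.

    Returns a tidy table with columns ``sample_id, animal, genotype,
    region, age_weeks, n_snv, n_del``.  One animal contributes one sample
    per region (the paper-style dissection design); the animal random
    effect is shared across that animal's regions.  With ``emit_reads``,
    per-sample SAM alignments, the genome FASTA, metadata and truth TSVs
    are written under ``out_dir``.
    """
    rng = np.random.default_rng(seed)
    snv_mult = dict(design.age_multipliers_snv)
    del_mult = dict(design.age_multipliers_del)
    rows = []
    genome = None
    if emit_reads:
        if out_dir is None:
            raise ConfigError("emit_reads requires out_dir")
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        gcfg = base_config or SimulationConfig(seed=seed, L=2000, depth=60.0)
        genome, _ = generate_genome(gcfg)

    for genotype in design.genotypes:
        for age in design.ages:
            for animal_idx in range(1, design.animals_per_cell + 1):
                animal_eff = float(np.exp(rng.normal(0.0, design.animal_sd)))
                for region in design.regions:
                    gr = 1.0
                    if (
                        genotype != design.genotypes[0]
                        and region in design.affected_regions
                        and age >= design.effect_onset_age
                    ):
                        gr = design.genotype_region_multiplier
                    mu_snv = design.baseline_snv * snv_mult[age] * gr * animal_eff
                    mu_del = design.baseline_del * del_mult[age] * gr * animal_eff
                    n_snv = int(rng.poisson(mu_snv))
                    n_del = int(rng.poisson(mu_del))
                    sample_id = f"{genotype}_{age}wk_a{animal_idx}_{region}"
                    rows.append(
                        dict(sample_id=sample_id, animal=animal_idx,
                             genotype=genotype, region=region, age_weeks=age,
                             n_snv=n_snv, n_del=n_del,
                             mu_snv=mu_snv, mu_del=mu_del)
                    )
    table = pd.DataFrame(rows)

    if emit_reads:
        from .circular import write_fasta

        write_fasta(out_dir / "genome.fa", {genome.name: genome.sequence})
        write_fasta(out_dir / "genome_dMT.fa",
                    {f"{genome.name}_dMT": genome.sequence * 2})
        truth_frames = []
        gcfg = base_config or SimulationConfig(seed=seed, L=2000, depth=60.0)
        for _, row in table.iterrows():
            srng = np.random.default_rng(
                np.random.SeedSequence(
                    [seed, zlib.crc32(row.sample_id.encode()) & 0x7FFFFFFF]
                )
            )
            n_snv = min(int(row.n_snv), genome.L // 20)
            positions = srng.choice(genome.L, size=n_snv, replace=False)
            plan = []
            for p in positions:
                ref = genome.sequence[int(p)]
                alt = srng.choice([b for b in "ACGT" if b != ref])
                frac = float(srng.uniform(0.05, 1.0))
                plan.append(SnvPlan(int(p), str(alt), frac))
            cfg = replace(gcfg, snv_plan=tuple(plan), seed=seed)
            records, truth = simulate_alignments(
                genome, cfg, rng=srng, sample_id=row.sample_id
            )
            write_sam(out_dir / f"{row.sample_id}.sam", records, genome)
            truth_frames.append(truth.to_frame())
        table.drop(columns=["mu_snv", "mu_del"]).to_csv(
            out_dir / "metadata.tsv", sep="\t", index=False
        )
        pd.concat(truth_frames, ignore_index=True).to_csv(
            out_dir / "truth.tsv", sep="\t", index=False
        )
    return table
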