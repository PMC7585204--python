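"""Variant extraction from alignments on the doubled circular reference.

Walks CIGAR strings to collect per-site mismatch evidence (SNVs) and
per-junction deletion evidence (``D`` operations and primary/supplementary
split pairs), normalizes all coordinates back onto the circle, merges
evidence arising in either tandem copy of the doubled reference without
double-counting fragments, applies the published post-filters, and splits
deletions into ordinary deletions (span <= 15 kb) and very-long-range
deletions / candidate multimers (span > 15 kb).

Support and depth are counted per *fragment* (read-pair name): a deletion
seen both as a ``D`` operation in one mate and as a split pair of the
same fragment contributes a single supporting observation.

Call-quality proxies (the upstream caller's internal score is not
reproducible): an SNV's quality is the mean phred of its supporting
bases; a deletion's quality is, per supporting fragment, the minimum of
the mean phreds of the two aligned segments flanking the junction,
averaged over supporting fragments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from collections import defaultdict

import numpy as np

from .circular import CircularGenome
from .simulate import (
    AlignmentRecord,
    FLAG_DUP,
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_PROPER,
    FLAG_SECONDARY,
    FLAG_UNMAPPED,
    VLRD_BOUNDARY,
    left_align_deletion,
)

logger = logging.getLogger(__name__)

DISCORDANT_MASK = (
    FLAG_PROPER | FLAG_UNMAPPED | FLAG_MATE_UNMAPPED | FLAG_SECONDARY | FLAG_DUP
)  # == 1294, the samtools -F mask

# published post-filter thresholds (minimum support / depth / quality)
SNV_MIN_SUPPORT = 4
SNV_MIN_DEPTH = 50
SNV_MIN_QUALITY = 20.0
DEL_MIN_SUPPORT = 2
DEL_MIN_DEPTH = 25
DEL_MIN_QUALITY = 10.0
MIN_ALLELE_FRACTION = 0.005


class MalformedRecordError(ValueError):
    pass


class DownsampleError(ValueError):
    pass


@dataclass(frozen=True)
class RawVariant:
    """A coordinate-normalized SNV or deletion call before filtering.

    ``pos5`` is the SNV site or the first deleted base (0-based, on the
    circle); ``pos3`` the first retained base after the gap (deletions).
    ``length`` is the junction's reference span on the doubled reference
    before normalization, so spans > 15 kb survive as such.
    """

    kind: str  # "SNV" | "DEL"
    pos5: int
    pos3: int | None
    length: int | None
    ref: str | None
    alt: str | None
    support: int
    depth: int
    quality: float

    @property
    def allele_fraction(self) -> float:
        return self.support / self.depth if self.depth else 0.0


@dataclass(frozen=True)
class ClassifiedVariant:
    variant: RawVariant
    vclass: str  # "SNV" | "DEL" | "VLRD"
    sample_id: str = ""

    def __getattr__(self, item):
        return getattr(self.variant, item)


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------

def downsample_alignments(records, target_n: int, seed: int,
                          sample_id: str = "") -> list:
    """Uniform random subset of exactly ``target_n`` mapped records.

    Mates are kept or dropped together (sampling acts on fragment names).
    Deterministic under ``seed``.
    """
    mapped = [r for r in records if not r.flags & FLAG_UNMAPPED]
    if target_n > len(mapped):
        raise DownsampleError(
            f"sample {sample_id or '<unnamed>'}: requested {target_n} reads "
            f"but only {len(mapped)} mapped records available"
        )
    if target_n == len(mapped):
        return list(mapped)
    groups = defaultdict(list)
    for r in mapped:
        groups[r.read_id].append(r)
    names = sorted(groups)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(names))
    chosen = []
    total = 0
    for idx in order:
        size = len(groups[names[idx]])
        if total + size <= target_n:
            chosen.append(names[idx])
            total += size
        if total == target_n:
            break
    if total != target_n:
        raise DownsampleError(
            f"sample {sample_id or '<unnamed>'}: cannot hit exactly "
            f"{target_n} records while keeping mates together"
        )
    keep = set(chosen)
    return [r for r in mapped if r.read_id in keep]


# ---------------------------------------------------------------------------
# CIGAR walking
# ---------------------------------------------------------------------------

def _walk_record(rec: AlignmentRecord, ref: np.ndarray, L: int,
                 trim_border: int):
    """Per-record evidence: (covered normalized positions, SNV events,
    deletion events, aligned segment list).

    SNV events are ``(pos, ref_base, alt_base, phred)``; deletion events
    are ``(pos5_raw, length)`` in doubled-reference coordinates.  Evidence
    within ``trim_border`` query bases of either read end is ignored.
    """
    qlen = rec.query_length
    if len(rec.seq) != qlen:
        raise MalformedRecordError(
            f"read {rec.read_id}: CIGAR consumes {qlen} query bases but "
            f"sequence has {len(rec.seq)}"
        )
    if rec.pos + rec.reference_span > 2 * L:
        raise MalformedRecordError(
            f"read {rec.read_id}: alignment runs past the doubled reference"
        )
    lo, hi = trim_border, qlen - trim_border
    qseq = np.frombuffer(rec.seq.encode(), np.uint8)
    qual = np.asarray(rec.qual, dtype=np.int32)

    covered = []
    snv_events = []
    del_events = []
    segments = []  # (ref_start, length, mean_phred) of M blocks
    qpos = 0
    rpos = rec.pos
    for op, n in rec.cigar:
        if op in "M=X":
            a = max(qpos, lo)
            b = min(qpos + n, hi)
            if b > a:
                roff = rpos + (a - qpos)
                block_ref = ref[roff : roff + (b - a)]
                block_q = qseq[a:b]
                pos_norm = (np.arange(roff, roff + (b - a)) % L).astype(np.int64)
                covered.append(pos_norm)
                mism = np.flatnonzero(block_q != block_ref)
                for m in mism:
                    snv_events.append(
                        (
                            int(pos_norm[m]),
                            chr(block_ref[m]),
                            chr(block_q[m]),
                            int(qual[a + m]),
                        )
                    )
            mean_q = float(qual[qpos : qpos + n].mean()) if n else 0.0
            segments.append((rpos, n, mean_q))
            qpos += n
            rpos += n
        elif op in "DN":
            if lo <= qpos <= hi:
                del_events.append((rpos, n))
            rpos += n
        elif op in "IS":
            qpos += n
        elif op in "HP":
            pass
        else:
            raise MalformedRecordError(
                f"read {rec.read_id}: unsupported CIGAR op {op!r}"
            )
    cov = np.concatenate(covered) if covered else np.empty(0, np.int64)
    return cov, snv_events, del_events, segments


def _del_quality(segments, pos5_raw: int) -> float:
    """min(mean phred left segment, mean phred right segment) at a junction."""
    left = [q for (s, n, q) in segments if s + n == pos5_raw]
    right_start = None
    right = []
    for s, n, q in segments:
        if s > pos5_raw and (right_start is None or s < right_start):
            right_start = s
            right = [q]
    if left and right:
        return min(left[0], right[0])
    vals = left or right or [0.0]
    return float(vals[0])


def _split_pair_junctions(parts):
    """Deletion junctions implied by primary + supplementary alignments of
    one read: ordered by reference position, each adjacent pair implies a
    junction from the left segment's end to the right segment's start."""
    events = []
    parts = sorted(parts, key=lambda rec: rec.pos)
    for left, right in zip(parts, parts[1:]):
        pos5_raw = left.pos + left.reference_span
        gap = right.pos - pos5_raw
        if gap >= 1:
            events.append((pos5_raw, gap))
    return events


def extract_variants(records, g: CircularGenome, trim_border: int = 5,
                     min_fraction: float = MIN_ALLELE_FRACTION) -> list[RawVariant]:
    """SNV and deletion calls from alignments on the doubled reference.

    Coordinates are normalized mod L; evidence for the same normalized
    variant in either dMT copy merges into one call, with support and
    depth counted once per fragment.
    """
    L = g.L
    ref = np.frombuffer((g.sequence + g.sequence).encode(), np.uint8)

    frag_cov: dict[str, set] = {}
    frag_snv: dict[tuple, dict[str, float]] = defaultdict(dict)
    frag_del: dict[tuple, dict[str, float]] = defaultdict(dict)
    supp_parts = defaultdict(list)

    usable = [
        r
        for r in records
        if not (r.flags & (FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_DUP))
    ]
    for rec in usable:
        cov, snv_events, del_events, segments = _walk_record(
            rec, ref, L, trim_border
        )
        frag = rec.read_id
        if cov.size:
            frag_cov.setdefault(frag, set()).update(np.unique(cov).tolist())
        for pos, rb, ab, q in snv_events:
            if ab == "N" or rb == "N":
                continue
            key = (pos, rb, ab)
            prev = frag_snv[key].get(frag)
            frag_snv[key][frag] = q if prev is None else (prev + q) / 2.0
        for pos5_raw, length in del_events:
            pos5 = left_align_deletion(g.sequence, pos5_raw % L, length)
            key = (pos5, length)
            q = _del_quality(segments, pos5_raw)
            prev = frag_del[key].get(frag)
            if prev is None or q > prev:
                frag_del[key][frag] = q
        if rec.is_supplementary:
            supp_parts[(rec.read_id, rec.is_read2)].append(rec)

    # pair supplementary parts with their primaries
    if supp_parts:
        primaries = defaultdict(list)
        for rec in usable:
            if not rec.is_supplementary:
                primaries[(rec.read_id, rec.is_read2)].append(rec)
        for key, extras in supp_parts.items():
            parts = primaries.get(key, []) + extras
            if len(parts) < 2:
                continue
            seg_quals = []
            for p in parts:
                _, _, _, segs = _walk_record(p, ref, L, trim_border)
                seg_quals.append(np.mean([q for (_, _, q) in segs]) if segs else 0.0)
            junction_q = float(min(seg_quals))
            for pos5_raw, length in _split_pair_junctions(parts):
                pos5 = left_align_deletion(g.sequence, pos5_raw % L, length)
                dkey = (pos5, length)
                frag = key[0]
                prev = frag_del[dkey].get(frag)
                if prev is None or junction_q > prev:
                    frag_del[dkey][frag] = junction_q

    # fragment-level coverage per circle position
    coverage = np.zeros(L, dtype=np.int64)
    for pos_set in frag_cov.values():
        coverage[np.fromiter(pos_set, np.int64, len(pos_set))] += 1

    variants: list[RawVariant] = []
    for (pos, rb, ab), support_map in sorted(frag_snv.items()):
        support = len(support_map)
        depth = int(coverage[pos])
        if depth == 0:
            continue
        frac = support / depth
        if frac < min_fraction:
            continue
        variants.append(
            RawVariant(
                kind="SNV", pos5=pos, pos3=None, length=None, ref=rb, alt=ab,
                support=support, depth=depth,
                quality=float(np.mean(list(support_map.values()))),
            )
        )
    for (pos5, length), support_map in sorted(frag_del.items()):
        support = len(support_map)
        depth = int(coverage[(pos5 - 1) % L])
        depth = max(depth, support)
        frac = support / depth if depth else 0.0
        if frac < min_fraction:
            continue
        variants.append(
            RawVariant(
                kind="DEL", pos5=pos5, pos3=(pos5 + length) % L, length=length,
                ref=None, alt=None, support=support, depth=depth,
                quality=float(np.mean(list(support_map.values()))),
            )
        )
    return variants


# ---------------------------------------------------------------------------
# Post-filters and classification
# ---------------------------------------------------------------------------

def apply_post_filters(
    variants,
    snv_min_support: int = SNV_MIN_SUPPORT,
    snv_min_depth: int = SNV_MIN_DEPTH,
    snv_min_quality: float = SNV_MIN_QUALITY,
    del_min_support: int = DEL_MIN_SUPPORT,
    del_min_depth: int = DEL_MIN_DEPTH,
    del_min_quality: float = DEL_MIN_QUALITY,
) -> list[RawVariant]:
    """Retain calls meeting the published minimums (inclusive comparisons).

    SNVs: support >= 4, depth >= 50, quality >= 20.  Deletions: support
    >= 2, depth >= 25, quality >= 10.  Order is preserved; per-filter
    rejection counts are logged.
    """
    kept = []
    rejected = defaultdict(int)
    for v in variants:
        if v.kind == "SNV":
            mins = (snv_min_support, snv_min_depth, snv_min_quality)
        else:
            mins = (del_min_support, del_min_depth, del_min_quality)
        checks = (
            ("support", v.support, mins[0]),
            ("depth", v.depth, mins[1]),
            ("quality", v.quality, mins[2]),
        )
        failed = [name for name, val, m in checks if val < m]
        if failed:
            for name in failed:
                rejected[f"{v.kind}:{name}"] += 1
        else:
            kept.append(v)
    if rejected:
        logger.info("post-filter rejections: %s", dict(rejected))
    return kept


def classify_deletions(variants, sample_id: str = "",
                       boundary: int = VLRD_BOUNDARY) -> list[ClassifiedVariant]:
    """Partition calls into SNV / DEL (span <= boundary) / VLRD (> boundary)."""
    out = []
    for v in variants:
        if v.kind == "SNV":
            vclass = "SNV"
        else:
            vclass = "DEL" if v.length <= boundary else "VLRD"
        out.append(ClassifiedVariant(variant=v, vclass=vclass, sample_id=sample_id))
    return out


def count_discordant(records) -> int:
    """Records with none of the -F 1294 bits set: mapped, mate mapped,
    primary, non-duplicate, and *not* properly paired."""
    n_unpaired = sum(1 for r in records if not r.flags & FLAG_PAIRED)
    if n_unpaired:
        logger.warning(
            "count_discordant: %d unpaired records; proper-pair semantics "
            "are undefined for them", n_unpaired,
        )
    return sum(1 for r in records if not r.flags & DISCORDANT_MASK)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

TSV_COLUMNS = [
    "sample_id", "class", "pos5_1based", "pos3_1based", "length", "ref",
    "alt", "support", "depth", "quality", "allele_fraction",
]


def variants_to_frame(classified):
    import pandas as pd

    rows = []  # one row per classified call, 1-based reporting coordinates
    for cv in classified:
        v = cv.variant
        rows.append(
            {
                "sample_id": cv.sample_id,
                "class": cv.vclass,
                "pos5_1based": v.pos5 + 1,
                "pos3_1based": (v.pos3 + 1) if v.pos3 is not None else "",
                "length": v.length if v.length is not None else "",
                "ref": v.ref or "",
                "alt": v.alt or "",
                "support": v.support,
                "depth": v.depth,
                "quality": round(v.quality, 2),
                "allele_fraction": round(v.allele_fraction, 6),
            }
        )
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def write_variants_tsv(classified, path) -> None:
    variants_to_frame(classified).to_csv(path, sep="\t", index=False)


def write_variants_vcf(classified, g: CircularGenome, path) -> None:
    """Minimal VCF 4.2: plain SNVs plus symbolic <DEL> records."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={g.name},length={g.L}>\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length">\n')
        fh.write('##INFO=<ID=VCLASS,Number=1,Type=String,Description="Class">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele fraction">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for cv in classified:
            v = cv.variant
            if v.kind == "SNV":
                fh.write(
                    f"{g.name}\t{v.pos5 + 1}\t.\t{v.ref}\t{v.alt}\t"
                    f"{v.quality:.1f}\t.\tVCLASS=SNV;AF={v.allele_fraction:.6f}\n"
                )
            else:
                anchor = (v.pos5 - 1) % g.L
                fh.write(
                    f"{g.name}\t{anchor + 1}\t.\t{g.sequence[anchor]}\t<DEL>\t"
                    f"{v.quality:.1f}\t.\t"
                    f"END={(v.pos3 or 0)};SVLEN=-{v.length};"
                    f"VCLASS={cv.vclass};AF={v.allele_fraction:.6f}\n"
                )
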