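"""Positional and categorical summaries of the mutation spectrum.

Bin-level SNV sharing across brain regions or animals, binned
allele-fraction profiles, cumulative position curves, the 12-class
substitution spectrum, per-gene length-normalized variant loads, the
VLRD-to-SNV proximity statistic, and cross-sample count normalization.
All positional summaries operate on normalized circle coordinates and
are rotation-invariant when coordinates are rotated with the genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import CircularGenome

SUBSTITUTION_CLASSES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)
TRANSITIONS = frozenset({"A>G", "G>A", "C>T", "T>C"})

# sharing-category presets: (lo, hi, label); hi None = open-ended
REGION_SHARING_CATEGORIES = ((1, 1, "1"), (2, 3, "2-3"), (4, 6, "4-6"))
ANIMAL_SHARING_CATEGORIES = ((1, 1, "1"), (2, 3, "2-3"), (4, None, ">=4"))


@dataclass(frozen=True)
class BinProfile:
    """Values over ceil(L / width) bins; the final bin may be partial."""

    bin_width: int
    values: tuple[float, ...]
    normalization: str  # none | max1 | fold_vs_reference
    partial_final_bin: bool


@dataclass(frozen=True)
class SpectrumTable:
    counts: dict
    transitions: int
    transversions: int

    @property
    def total(self) -> int:
        return self.transitions + self.transversions

    def collapsed(self) -> dict:
        """Six pyrimidine-context classes (reverse-complement pairs merged)."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        out: dict[str, int] = {}
        for cls, n in self.counts.items():
            r, a = cls.split(">")
            if r in "AG":  # fold purines onto the pyrimidine strand
                cls = f"{comp[r]}>{comp[a]}"
            out[cls] = out.get(cls, 0) + n
        return out


def _bin_index(pos: int, width: int) -> int:
    return pos // width


def snv_sharing(groups: dict, L: int, bin_width: int = 10,
                categories=REGION_SHARING_CATEGORIES) -> dict:
    """How many groups (regions or animals) share each occupied SNV bin.

    ``groups`` maps a group label to its SNV positions.  Multiple SNVs
    from one group in one bin count as a single instance.  Returns the
    per-category bin counts, the per-bin sharing levels, and the total
    number of occupied bins.
    """
    if bin_width < 1:
        raise ValueError("bin width must be >= 1")
    n_bins = math.ceil(L / bin_width)
    presence = np.zeros(n_bins, dtype=np.int64)
    for positions in groups.values():
        bins = {_bin_index(p % L, bin_width) for p in positions}
        for b in bins:
            presence[b] += 1
    occupied = np.flatnonzero(presence)
    hist: dict[str, int] = {}
    for lo, hi, label in categories:
        sel = presence[occupied] >= lo
        if hi is not None:
            sel &= presence[occupied] <= hi
        hist[label] = int(sel.sum())
    return {
        "histogram": hist,
        "occupied_bins": int(len(occupied)),
        "levels": {int(b): int(presence[b]) for b in occupied},
    }


def binned_allele_fraction(snvs, L: int, bin_width: int = 100) -> BinProfile:
    """Per-bin summed allele fraction, scaled so the highest bin is 1.

    ``snvs`` yields (position, allele_fraction).  An empty input returns
    an all-zero, explicitly unnormalized profile.
    """
    n_bins = math.ceil(L / bin_width)
    values = np.zeros(n_bins)
    any_snv = False
    for pos, frac in snvs:
        values[_bin_index(pos % L, bin_width)] += frac
        any_snv = True
    norm = "none"
    if any_snv and values.max() > 0:
        values = values / values.max()
        norm = "max1"
    return BinProfile(
        bin_width=bin_width,
        values=tuple(float(v) for v in values),
        normalization=norm,
        partial_final_bin=(L % bin_width != 0),
    )


def cumulative_position(positions, L: int):
    """Cumulative percentage curve of variant positions over [0, L).

    Returns ``(xs, pct)``: after position ``xs[i]``, ``pct[i]`` percent of
    the variants lie at or before it.  Monotone, reaching 100 at the last
    occupied position.
    """
    positions = sorted(p % L for p in positions)
    if not positions:
        raise ValueError("empty variant set")
    xs, counts = np.unique(positions, return_counts=True)
    pct = 100.0 * np.cumsum(counts) / len(positions)
    return xs.astype(int), pct


def mutation_spectrum(snvs, g: CircularGenome) -> SpectrumTable:
    """12-class substitution counts on the reference strand.

    ``snvs`` yields (pos, ref, alt).  A ref base disagreeing with the
    genome raises a consistency error.
    """
    counts = {cls: 0 for cls in SUBSTITUTION_CLASSES}
    for pos, ref, alt in snvs:
        if g.sequence[pos % g.L] != ref:
            raise ValueError(
                f"SNV ref base {ref} at {pos} disagrees with genome "
                f"({g.sequence[pos % g.L]})"
            )
        counts[f"{ref}>{alt}"] += 1
    ti = sum(n for cls, n in counts.items() if cls in TRANSITIONS)
    tv = sum(n for cls, n in counts.items() if cls not in TRANSITIONS)
    return SpectrumTable(counts=counts, transitions=ti, transversions=tv)


def _overlaps_gene(pos5: int, length: int, gene, L: int) -> bool:
    """Does the deleted arc [pos5, pos5+length) intersect the gene arc?"""
    gene_len = gene.length(L)
    off = (gene.start - pos5) % L
    if off < length:  # gene start inside deletion
        return True
    off2 = (pos5 - gene.start) % L
    return off2 < gene_len  # deletion start inside gene


def per_gene_load(classified, g: CircularGenome, weight: str = "count") -> dict:
    """Length-normalized per-gene SNV and deletion loads, min-max scaled.

    SNV load: SNVs inside the gene / gene length.  Deletion load:
    deletions whose deleted arc overlaps the gene / gene length.  With
    ``weight='allele_fraction'`` each variant contributes its fraction
    instead of 1.  Returns the scaled vectors and their Pearson r/p.
    """
    from .stats import pearson

    if not g.genes:
        raise ValueError("genome carries no gene annotation")
    genes = list(g.genes)
    snv_load = np.zeros(len(genes))
    del_load = np.zeros(len(genes))
    for cv in classified:
        w = cv.allele_fraction if weight == "allele_fraction" else 1.0
        if cv.vclass == "SNV":
            for gi, gene in enumerate(genes):
                if gene.contains(cv.pos5, g.L):
                    snv_load[gi] += w
        else:
            for gi, gene in enumerate(genes):
                if _overlaps_gene(cv.pos5, cv.length, gene, g.L):
                    del_load[gi] += w
    lengths = np.array([gene.length(g.L) for gene in genes], float)
    snv_load /= lengths
    del_load /= lengths

    def _scale(v):
        rng = v.max() - v.min()
        return (v - v.min()) / rng if rng > 0 else np.zeros_like(v)

    snv_scaled = _scale(snv_load)
    del_scaled = _scale(del_load)
    corr = {"r": None, "p": None}
    if len(genes) >= 3 and np.ptp(snv_scaled) > 0 and np.ptp(del_scaled) > 0:
        corr = pearson(snv_scaled, del_scaled)
    return {
        "genes": [gene.gene_id for gene in genes],
        "snv_load": snv_scaled.tolist(),
        "del_load": del_scaled.tolist(),
        "r": corr["r"],
        "p": corr["p"],
    }


def vlrd_snv_proximity(vlrd_pos5, snv_pos, L: int) -> dict:
    """Distance from each VLRD 5' breakpoint to its nearest SNV.

    Returns mean, SD, and the fraction of breakpoints co-positioned
    (distance exactly 0) with an SNV.
    """
    vlrds = list(vlrd_pos5)
    snvs = np.array(sorted({p % L for p in snv_pos}), dtype=np.int64)
    if not vlrds or snvs.size == 0:
        raise ValueError("need non-empty VLRD and SNV sets")
    dists = []
    for p in vlrds:
        d = (p - snvs) % L
        dists.append(int(np.minimum(d, L - d).min()))
    dists = np.array(dists)
    return {
        "mean_bp": float(dists.mean()),
        "sd_bp": float(dists.std(ddof=1)) if len(dists) > 1 else 0.0,
        "co_position_fraction": float((dists == 0).mean()),
        "n": int(len(dists)),
    }


def normalize_counts(cohort: pd.DataFrame, value: str,
                     mode: str = "fold_vs_10wk_mean",
                     reference_age: int = 10,
                     reference_genotype: str | None = None) -> pd.DataFrame:
    """Cross-sample count normalization.

    ``fold_vs_10wk_mean``: divide by the mean of the reference-age (and
    optionally reference-genotype) samples.  ``min_sample``: divide by
    the smallest sample's count, which then maps to 1.0.
    """
    out = cohort.copy()
    if mode == "fold_vs_10wk_mean":
        ref = out[out["age_weeks"] == reference_age]
        if reference_genotype is not None:
            ref = ref[ref["genotype"] == reference_genotype]
        denom = ref[value].mean()
    elif mode == "min_sample":
        denom = out[value].min()
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if not denom or not np.isfinite(denom):
        raise ValueError(
            f"normalization reference for {value!r} is zero or undefined"
        )
    out[f"{value}_norm"] = out[value] / denom
    return out
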