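"""CIGAR walking, dMT merging, filtering, classification, downsampling."""

from dataclasses import replace

import numpy as np
import pytest

from mtspectrum.circular import CircularGenome
from mtspectrum.extract import (
    DownsampleError,
    MalformedRecordError,
    RawVariant,
    apply_post_filters,
    classify_deletions,
    count_discordant,
    downsample_alignments,
    extract_variants,
)
from mtspectrum.simulate import (
    AlignmentRecord,
    FLAG_PAIRED,
    FLAG_PROPER,
    FLAG_READ1,
    FLAG_READ2,
    FLAG_SECONDARY,
    FLAG_SUPPLEMENTARY,
    SimulationConfig,
    generate_genome,
)
from conftest import random_sequence


def _genome(L=400, seed=0):
    rng = np.random.default_rng(seed)
    return CircularGenome("g", random_sequence(rng, L))


def _read(g, pos, cigar, read_id="r1", flags=0, mutate=None):
    """Build a record whose sequence matches the doubled reference except
    at the query offsets given in ``mutate`` ({offset: base})."""
    doubled = g.sequence * 2
    seq = []
    rpos = pos
    for op, n in cigar:
        if op in "M=X":
            seq.append(doubled[rpos : rpos + n])
            rpos += n
        elif op in "DN":
            rpos += n
        elif op in "IS":
            seq.append("A" * n)
    seq = list("".join(seq))
    for off, base in (mutate or {}).items():
        seq[off] = base
    return AlignmentRecord(read_id=read_id, flags=flags, pos=pos,
                           cigar=tuple(cigar), seq="".join(seq),
                           qual=tuple([30] * len(seq)))


class TestExtractVariants:
    def test_matching_read_yields_nothing(self):
        g = _genome()
        recs = [_read(g, 10, [("M", 50)])]
        assert extract_variants(recs, g) == []

    def test_cigar_deletion_arithmetic(self):
        g = _genome()
        p = 30
        recs = [_read(g, p, [("M", 20), ("D", 100), ("M", 130)], "a"),
                _read(g, p, [("M", 20), ("D", 100), ("M", 130)], "b")]
        out = extract_variants(recs, g)
        dels = [v for v in out if v.kind == "DEL"]
        assert len(dels) == 1
        v = dels[0]
        # left-alignment may shift the breakpoint; length never changes
        assert v.length == 100
        assert v.support == 2
        from mtspectrum.simulate import left_align_deletion

        assert v.pos5 == left_align_deletion(g.sequence, (p + 20) % g.L, 100)

    def test_dmt_copies_merge_into_one_variant(self):
        g = _genome()
        p = 50
        cigar = [("M", 20), ("D", 60), ("M", 40)]
        recs = [_read(g, p, cigar, "copy1"), _read(g, p + g.L, cigar, "copy2")]
        out = extract_variants(recs, g)
        dels = [v for v in out if v.kind == "DEL"]
        assert len(dels) == 1
        assert dels[0].support == 2

    def test_snv_trim_border_excludes_read_end_evidence(self):
        g = _genome()
        rec_edge = _read(g, 0, [("M", 50)], "edge", mutate={2: "N"})
        # place a real mismatch at offset 2 (inside border 5) and at 25
        base_mid = "ACGT"[("ACGT".index(g.sequence[25]) + 1) % 4]
        base_edge = "ACGT"[("ACGT".index(g.sequence[2]) + 1) % 4]
        rec = _read(g, 0, [("M", 50)], "r", mutate={2: base_edge, 25: base_mid})
        out = extract_variants([rec], g)
        assert [(v.pos5, v.alt) for v in out] == [(25, base_mid)]

    def test_split_supplementary_pair_junction(self):
        g = _genome()
        primary = _read(g, 10, [("M", 60), ("S", 90)], "frag",
                        flags=FLAG_PAIRED | FLAG_READ1)
        supp = _read(g, 200, [("S", 60), ("M", 90)], "frag",
                     flags=FLAG_PAIRED | FLAG_READ1 | FLAG_SUPPLEMENTARY)
        out = extract_variants([primary, supp], g)
        dels = [v for v in out if v.kind == "DEL"]
        assert len(dels) == 1
        assert dels[0].length == 200 - 70

    def test_d_and_split_evidence_from_same_fragment_counted_once(self):
        g = _genome()
        from mtspectrum.simulate import left_align_deletion

        pos5_raw, ln = 70, 130
        cigar_read = _read(g, 10, [("M", 60), ("D", ln), ("M", 40)], "frag",
                           flags=FLAG_PAIRED | FLAG_READ1)
        supp_a = _read(g, 10, [("M", 60), ("S", 40)], "frag",
                       flags=FLAG_PAIRED | FLAG_READ2)
        supp_b = _read(g, pos5_raw + ln, [("S", 60), ("M", 40)], "frag",
                       flags=FLAG_PAIRED | FLAG_READ2 | FLAG_SUPPLEMENTARY)
        out = extract_variants([cigar_read, supp_a, supp_b], g)
        dels = [v for v in out if v.kind == "DEL"]
        assert len(dels) == 1
        assert dels[0].support == 1  # one fragment, however many evidences

    def test_malformed_cigar_raises_with_read_id(self):
        g = _genome()
        rec = _read(g, 0, [("M", 50)], "broken")
        rec = replace(rec, seq=rec.seq[:-1])
        with pytest.raises(MalformedRecordError, match="broken"):
            extract_variants([rec], g)

    def test_min_allele_fraction_cut(self):
        g = _genome(L=300)
        base = "ACGT"[("ACGT".index(g.sequence[150]) + 1) % 4]
        recs = [_read(g, 100, [("M", 100)], f"r{i}") for i in range(300)]
        recs.append(_read(g, 100, [("M", 100)], "mut", mutate={50: base}))
        out = extract_variants(recs, g, min_fraction=0.005)
        assert [v for v in out if v.kind == "SNV"] == []
        out2 = extract_variants(recs, g, min_fraction=0.001)
        assert len([v for v in out2 if v.kind == "SNV"]) == 1


def _rv(kind, support, depth, quality, length=None):
    return RawVariant(kind=kind, pos5=10, pos3=(10 + length) % 400 if length
                      else None, length=length, ref="A" if kind == "SNV" else None,
                      alt="C" if kind == "SNV" else None, support=support,
                      depth=depth, quality=quality)


class TestPostFilters:
    @pytest.mark.parametrize(
        "kind,support,depth,quality,length,kept",
        [
            ("SNV", 3, 60, 25.0, None, False),   # support below minimum
            ("SNV", 4, 50, 20.0, None, True),    # inclusive boundary
            ("SNV", 4, 49, 25.0, None, False),
            ("SNV", 4, 50, 19.9, None, False),
            ("DEL", 1, 30, 15.0, 100, False),
            ("DEL", 2, 25, 10.0, 100, True),     # inclusive boundary
            ("DEL", 2, 24, 15.0, 100, False),
            ("DEL", 2, 25, 9.9, 100, False),
        ],
    )
    def test_boundaries(self, kind, support, depth, quality, length, kept):
        out = apply_post_filters([_rv(kind, support, depth, quality, length)])
        assert bool(out) is kept

    def test_empty_input(self):
        assert apply_post_filters([]) == []

    def test_order_preserved(self):
        vs = [_rv("SNV", 10, 100, 30.0), _rv("DEL", 5, 50, 20.0, 10),
              _rv("SNV", 6, 80, 25.0)]
        out = apply_post_filters(vs)
        assert out == vs


class TestClassifyDeletions:
    def test_boundary_lengths(self):
        vs = [_rv("DEL", 5, 50, 20.0, 15000), _rv("DEL", 5, 50, 20.0, 15001)]
        out = classify_deletions(vs)
        assert [cv.vclass for cv in out] == ["DEL", "VLRD"]

    def test_partition(self, rng):
        lengths = rng.integers(1, 17000, 50)
        vs = [_rv("DEL", 5, 50, 20.0, int(ln)) for ln in lengths]
        out = classify_deletions(vs)
        assert len(out) == len(vs)
        for cv, ln in zip(out, lengths):
            assert cv.vclass == ("DEL" if ln <= 15000 else "VLRD")

    def test_snvs_pass_through(self):
        out = classify_deletions([_rv("SNV", 5, 60, 30.0)], sample_id="s")
        assert out[0].vclass == "SNV" and out[0].sample_id == "s"


class TestCountDiscordant:
    def _pair(self, flags1, flags2):
        q = tuple([30] * 10)
        return [
            AlignmentRecord("p", flags1, 0, (("M", 10),), "A" * 10, q),
            AlignmentRecord("p", flags2, 100, (("M", 10),), "A" * 10, q),
        ]

    def test_proper_pairs_not_counted(self):
        recs = self._pair(FLAG_PAIRED | FLAG_PROPER | FLAG_READ1,
                          FLAG_PAIRED | FLAG_PROPER | FLAG_READ2)
        assert count_discordant(recs) == 0

    def test_mapped_non_proper_pair_counts_both_mates(self):
        recs = self._pair(FLAG_PAIRED | FLAG_READ1, FLAG_PAIRED | FLAG_READ2)
        assert count_discordant(recs) == 2

    def test_secondary_never_counted(self):
        recs = self._pair(FLAG_PAIRED | FLAG_READ1 | FLAG_SECONDARY,
                          FLAG_PAIRED | FLAG_READ2 | FLAG_SECONDARY)
        assert count_discordant(recs) == 0


class TestDownsample:
    def _records(self, n_pairs, g):
        recs = []
        for i in range(n_pairs):
            recs.append(_read(g, 10, [("M", 20)], f"f{i}",
                              flags=FLAG_PAIRED | FLAG_READ1))
            recs.append(_read(g, 60, [("M", 20)], f"f{i}",
                              flags=FLAG_PAIRED | FLAG_READ2))
        return recs

    def test_identity_when_target_equals_n(self):
        g = _genome()
        recs = self._records(10, g)
        out = downsample_alignments(recs, 20, seed=1)
        assert sorted(id(r) for r in out) == sorted(id(r) for r in recs)

    def test_deterministic_under_seed(self):
        g = _genome()
        recs = self._records(20, g)
        a = downsample_alignments(recs, 20, seed=5)
        b = downsample_alignments(recs, 20, seed=5)
        assert [(r.read_id, r.flags) for r in a] == \
            [(r.read_id, r.flags) for r in b]

    def test_pairs_kept_together(self):
        g = _genome()
        recs = self._records(20, g)
        out = downsample_alignments(recs, 10, seed=2)
        from collections import Counter

        counts = Counter(r.read_id for r in out)
        assert all(v == 2 for v in counts.values())

    def test_target_too_large(self):
        g = _genome()
        recs = self._records(5, g)
        with pytest.raises(DownsampleError, match="mysample"):
            downsample_alignments(recs, 11, seed=0, sample_id="mysample")

    def test_inclusion_frequency_uniform(self):
        g = _genome()
        n_pairs, target_pairs = 20, 10
        recs = self._records(n_pairs, g)
        hits = {f"f{i}": 0 for i in range(n_pairs)}
        n_seeds = 200
        for seed in range(n_seeds):
            out = downsample_alignments(recs, 2 * target_pairs, seed=seed)
            for name in {r.read_id for r in out}:
                hits[name] += 1
        p = target_pairs / n_pairs
        sd = np.sqrt(p * (1 - p) / n_seeds)
        for name, h in hits.items():
            assert abs(h / n_seeds - p) < 4 * sd, name
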