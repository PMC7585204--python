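"""Positional summaries, substitution spectrum, gene loads, proximity."""

import numpy as np
import pytest

from _oracles import oracle_nearest_snv_distance
from conftest import random_sequence
from mtspectrum.circular import CircularGenome, GeneAnnotation
from mtspectrum.spectrum import (
    ANIMAL_SHARING_CATEGORIES,
    binned_allele_fraction,
    cumulative_position,
    mutation_spectrum,
    normalize_counts,
    per_gene_load,
    snv_sharing,
    vlrd_snv_proximity,
)


class TestSnvSharing:
    def test_single_snv_single_region(self):
        out = snv_sharing({"COR": [42]}, L=1000)
        assert out["histogram"] == {"1": 1, "2-3": 0, "4-6": 0}

    def test_two_snvs_same_bin_count_once(self):
        out = snv_sharing({"COR": [3, 7]}, L=1000, bin_width=10)
        assert out["occupied_bins"] == 1
        assert out["histogram"]["1"] == 1

    def test_identical_lists_across_six_regions_max_category(self):
        positions = [10, 250, 777]
        groups = {r: list(positions) for r in
                  ("COR", "CP", "DR", "NAc", "PVT", "SN")}
        out = snv_sharing(groups, L=1000)
        assert out["histogram"] == {"1": 0, "2-3": 0, "4-6": 3}

    def test_animal_preset_open_ended(self):
        groups = {f"a{i}": [5] for i in range(5)}
        out = snv_sharing(groups, L=100,
                          categories=ANIMAL_SHARING_CATEGORIES)
        assert out["histogram"][">=4"] == 1

    def test_histogram_totals_equal_occupied_bins(self, rng):
        groups = {
            f"g{i}": rng.integers(0, 1000, 30).tolist() for i in range(4)
        }
        out = snv_sharing(groups, L=1000)
        assert sum(out["histogram"].values()) == out["occupied_bins"]

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            snv_sharing({"a": [1]}, L=100, bin_width=0)


class TestBinnedAlleleFraction:
    def test_single_snv_peak_is_one(self):
        prof = binned_allele_fraction([(150, 0.3)], L=1000)
        assert prof.values[1] == 1.0
        assert sum(prof.values) == 1.0
        assert prof.normalization == "max1"

    def test_max_scaling(self):
        prof = binned_allele_fraction([(10, 0.2), (150, 0.4)], L=1000)
        assert prof.values[0] == pytest.approx(0.5)
        assert prof.values[1] == pytest.approx(1.0)

    def test_empty_input_unnormalized_zero(self):
        prof = binned_allele_fraction([], L=950)
        assert all(v == 0.0 for v in prof.values)
        assert prof.normalization == "none"
        assert prof.partial_final_bin


class TestCumulativePosition:
    def test_point_mass_step(self):
        xs, pct = cumulative_position([400, 400, 400], L=1000)
        assert list(xs) == [400]
        assert list(pct) == [100.0]

    def test_monotone_and_reaches_100(self, rng):
        xs, pct = cumulative_position(rng.integers(0, 1000, 200), L=1000)
        assert np.all(np.diff(pct) >= 0)
        assert pct[-1] == pytest.approx(100.0)

    def test_uniform_positions_near_diagonal(self, rng):
        n = 2000
        pos = rng.integers(0, 10_000, n)
        xs, pct = cumulative_position(pos, L=10_000)
        # Kolmogorov band around the diagonal at alpha ~ 1e-3
        dev = np.max(np.abs(pct / 100.0 - (xs + 1) / 10_000))
        assert dev < 1.95 / np.sqrt(n)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            cumulative_position([], L=100)


class TestMutationSpectrum:
    def test_single_transition(self):
        g = CircularGenome("g", "CCCC" + "A" * 96)
        spec = mutation_spectrum([(1, "C", "T")], g)
        assert spec.transitions == 1 and spec.transversions == 0

    def test_counts_sum_to_input(self, rng):
        g = CircularGenome("g", random_sequence(rng, 500))
        snvs = []
        for p in rng.choice(500, 60, replace=False):
            ref = g.sequence[p]
            alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
            snvs.append((int(p), ref, alt))
        spec = mutation_spectrum(snvs, g)
        assert sum(spec.counts.values()) == 60
        assert spec.total == 60

    def test_planted_spectrum_recovered_exactly(self, rng):
        g = CircularGenome("g", random_sequence(rng, 2000))
        transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
        snvs = []
        want_ti = 0
        for p in rng.choice(2000, 100, replace=False):
            ref = g.sequence[p]
            if rng.random() < 0.7:
                snvs.append((int(p), ref, transitions[ref]))
                want_ti += 1
            else:
                tv = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
                snvs.append((int(p), ref, tv))
        spec = mutation_spectrum(snvs, g)
        assert spec.transitions == want_ti
        assert spec.transversions == 100 - want_ti

    def test_collapsed_view_merges_complements(self):
        g = CircularGenome("g", "GA" + "C" * 98)
        spec = mutation_spectrum([(0, "G", "A"), (1, "A", "G")], g)
        collapsed = spec.collapsed()
        assert collapsed["C>T"] == 1 and collapsed["T>C"] == 1

    def test_ref_disagreement_raises(self):
        g = CircularGenome("g", "AAAA" + "C" * 96)
        with pytest.raises(ValueError):
            mutation_spectrum([(0, "G", "T")], g)


def _cv(vclass, pos5, length=None, fraction=0.5):
    from mtspectrum.extract import ClassifiedVariant, RawVariant

    v = RawVariant(kind="SNV" if vclass == "SNV" else "DEL", pos5=pos5,
                   pos3=None if vclass == "SNV" else (pos5 + length) % 1000,
                   length=length, ref="A" if vclass == "SNV" else None,
                   alt="G" if vclass == "SNV" else None, support=5,
                   depth=10, quality=30.0)
    return ClassifiedVariant(variant=v, vclass=vclass)


class TestPerGeneLoad:
    def _genome(self, n_genes=5, L=1000):
        width = L // n_genes
        genes = tuple(
            GeneAnnotation(f"g{i}", i * width, (i + 1) * width, "protein")
            for i in range(n_genes)
        )
        return CircularGenome("g", "A" * L, genes)

    def test_single_gene_concentration(self):
        g = self._genome()
        load = per_gene_load([_cv("SNV", 50), _cv("SNV", 60)], g)
        assert load["snv_load"][0] == 1.0
        assert all(v == 0.0 for v in load["snv_load"][1:])

    def test_deletion_spanning_three_genes_increments_each(self):
        g = self._genome()
        # deletion [150, 550) overlaps genes 0,1,2 (bins of 200)
        load = per_gene_load([_cv("DEL", 150, 400)], g)
        assert [v > 0 for v in load["del_load"]] == \
            [True, True, True, False, False]

    def test_origin_wrapping_deletion_overlap(self):
        g = self._genome()
        load = per_gene_load([_cv("DEL", 900, 200)], g)  # wraps into gene 0
        assert load["del_load"][0] > 0 and load["del_load"][4] > 0
        assert all(v == 0 for v in load["del_load"][1:4])

    def test_planted_correlated_loads(self, rng):
        L, n = 2000, 20
        width = L // n
        genes = tuple(GeneAnnotation(f"g{i}", i * width, (i + 1) * width)
                      for i in range(n))
        g = CircularGenome("g", "A" * L, genes)
        variants = []
        weights = rng.integers(0, 10, n)
        for i, w in enumerate(weights):
            for _ in range(int(w)):
                variants.append(_cv("SNV", i * width + 5))
                variants.append(_cv("DEL", i * width + 10, 20))
        load = per_gene_load(variants, g)
        assert load["r"] > 0.8

    def test_no_genes_error(self):
        g = CircularGenome("g", "A" * 200)
        with pytest.raises(ValueError):
            per_gene_load([], g)


class TestVlrdSnvProximity:
    def test_co_positioned(self):
        out = vlrd_snv_proximity([10, 20], [10, 20, 500], L=1000)
        assert out["mean_bp"] == 0.0
        assert out["co_position_fraction"] == 1.0

    def test_midway_breakpoint_takes_min_arc(self):
        out = vlrd_snv_proximity([100], [40, 170], L=1000)
        assert out["mean_bp"] == 60.0

    def test_matches_bruteforce_scan(self, rng):
        L = 500
        snvs = rng.choice(L, 30, replace=False).tolist()
        vlrds = rng.integers(0, L, 20).tolist()
        out = vlrd_snv_proximity(vlrds, snvs, L)
        expected = [oracle_nearest_snv_distance(p, snvs, L) for p in vlrds]
        assert out["mean_bp"] == pytest.approx(np.mean(expected))
        assert out["co_position_fraction"] == pytest.approx(
            np.mean([d == 0 for d in expected]))

    def test_empty_sets_error(self):
        with pytest.raises(ValueError):
            vlrd_snv_proximity([], [1], 100)
        with pytest.raises(ValueError):
            vlrd_snv_proximity([1], [], 100)


class TestNormalizeCounts:
    def _table(self):
        import pandas as pd

        return pd.DataFrame({
            "sample_id": ["a", "b", "c", "d"],
            "age_weeks": [10, 10, 50, 50],
            "genotype": ["WT"] * 4,
            "n_snv": [8, 12, 30, 50],
        })

    def test_fold_vs_reference_mean(self):
        out = normalize_counts(self._table(), "n_snv")
        assert out.loc[2, "n_snv_norm"] == pytest.approx(3.0)

    def test_min_sample_maps_to_one(self):
        out = normalize_counts(self._table(), "n_snv", mode="min_sample")
        assert out["n_snv_norm"].min() == pytest.approx(1.0)

    def test_rank_order_preserved(self):
        table = self._table()
        out = normalize_counts(table, "n_snv")
        assert list(out["n_snv_norm"].rank()) == list(table["n_snv"].rank())

    def test_zero_reference_error(self):
        table = self._table()
        table.loc[table.age_weeks == 10, "n_snv"] = 0
        with pytest.raises(ValueError):
            normalize_counts(table, "n_snv")
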