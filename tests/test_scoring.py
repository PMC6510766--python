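"""Signature construction and the log2 fraction-ratio score."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import random_peakset
from remi import (
    GenomicInterval,
    PeakSet,
    Signature,
    TFCatalogue,
    binomial_score_se,
    build_signature,
    reference_from_average,
    score_subset_vs_all,
    score_vs_reference,
)


def iv(chrom, start, end, id_):
    return GenomicInterval(chrom, start, end, id_)


def random_signature(rng, factors, name="sig"):
    n = int(rng.integers(50, 5000))
    return Signature(
        population_name=name,
        n_peaks=n,
        per_factor_count={f: int(rng.integers(0, n + 1)) for f in factors},
    )


class TestBuildSignature:
    def test_direct_count(self):
        pop = PeakSet([iv("chr1", i * 100, i * 100 + 50, f"p{i}") for i in range(4)])
        cat = TFCatalogue(
            [
                ("X", iv("chr1", 10, 20, "s1")),
                ("X", iv("chr1", 15, 25, "s1b")),  # same peak: still counts once
                ("X", iv("chr1", 110, 120, "s2")),
                ("Y", iv("chr2", 10, 20, "s3")),
            ]
        )
        sig = build_signature(pop, cat)
        assert sig.per_factor_count == {"X": 2, "Y": 0}
        assert sig.per_factor_fraction["X"] == 0.5

    def test_empty_population_rejected(self):
        cat = TFCatalogue([("X", iv("chr1", 0, 10, "s"))])
        with pytest.raises(ValueError, match="empty population"):
            build_signature(PeakSet([]), cat)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        pop = random_peakset(rng, 2000, max_start=200_000, name="pop")
        factors = [f"F{k:02d}" for k in range(20)]
        entries = []
        for k, f in enumerate(factors):
            sites = random_peakset(
                rng, 150, max_start=200_000, max_width=30, name=f"s{k}_"
            )
            entries.extend((f, s) for s in sites)
        cat = TFCatalogue(entries)
        sig = build_signature(pop, cat)
        for f in factors:
            sites = cat.sites_for(f)
            expected = sum(
                any(p.overlap_bp(s) >= 1 for s in sites) for p in pop
            )
            assert sig.per_factor_count[f] == expected


class TestScoreVsReference:
    def test_self_score_is_zero(self, rng):
        sig = random_signature(rng, ["A", "B", "C"])
        profile = score_vs_reference(sig, sig)
        assert all(s == 0.0 for s in profile.scores.values())

    def test_arithmetic_log_ratio(self):
        t = Signature("t", 100_000, {"X": 40_000})
        r = Signature("r", 100_000, {"X": 20_000})
        profile = score_vs_reference(t, r, pseudocount=0.5)
        assert profile.scores["X"] == pytest.approx(1.0, abs=1e-4)

    def test_zero_in_both_scores_zero(self):
        t = Signature("t", 100, {"X": 0, "Y": 50})
        r = Signature("r", 200, {"X": 0, "Y": 100})
        profile = score_vs_reference(t, r)
        assert profile.scores["X"] == 0.0

    def test_mismatched_factors_error_lists_difference(self):
        t = Signature("t", 10, {"X": 1})
        r = Signature("r", 10, {"Y": 1})
        with pytest.raises(ValueError, match="X"):
            score_vs_reference(t, r)

    def test_ranked_output_most_enriched_first(self):
        t = Signature("t", 1000, {"up": 400, "flat": 100, "down": 20})
        r = Signature("r", 1000, {"up": 100, "flat": 100, "down": 100})
        profile = score_vs_reference(t, r)
        assert list(profile.scores) == ["up", "flat", "down"]
        frame = profile.to_frame()
        assert frame["rank"].tolist() == [1, 2, 3]

    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry_property(self, seed):
        rng = np.random.default_rng(seed)
        factors = ["A", "B", "C", "D"]
        s1 = random_signature(rng, factors, "s1")
        s2 = random_signature(rng, factors, "s2")
        p12 = score_vs_reference(s1, s2)
        p21 = score_vs_reference(s2, s1)
        for f in factors:
            assert p12.scores[f] == pytest.approx(-p21.scores[f], abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_test_fraction(self, seed):
        rng = np.random.default_rng(seed)
        ref = random_signature(rng, ["F"], "ref")
        n = 500
        counts = sorted(int(rng.integers(0, n + 1)) for _ in range(5))
        scores = [
            score_vs_reference(Signature("t", n, {"F": c}), ref).scores["F"]
            for c in counts
        ]
        assert all(a <= b + 1e-12 for a, b in zip(scores, scores[1:]))


class TestReferenceFromAverage:
    def test_single_signature_is_identity(self):
        sig = Signature("s", 100, {"X": 30})
        avg = reference_from_average([sig])
        assert avg.n_peaks == 100
        assert avg.per_factor_fraction == sig.per_factor_fraction

    def test_mean_of_fractions(self):
        s1 = Signature("s1", 100, {"X": 20})
        s2 = Signature("s2", 200, {"X": 80})
        avg = reference_from_average([s1, s2])
        assert avg.per_factor_fraction["X"] == pytest.approx(0.3)
        assert avg.n_peaks == 150

    def test_matches_direct_recomputation(self, rng):
        factors = ["A", "B", "C"]
        sigs = [random_signature(rng, factors, f"s{i}") for i in range(5)]
        avg = reference_from_average(sigs)
        for f in factors:
            expected = np.mean([s.per_factor_fraction[f] for s in sigs])
            assert avg.per_factor_fraction[f] == pytest.approx(expected)


class TestScoreSubsetVsAll:
    def _catalogued_universe(self, rng, n=2000, planted="Q"):
        """Universe whose first half exclusively carries factor `planted`."""
        universe = random_peakset(rng, n, max_start=500_000, name="u")
        entries = []
        half = {ivx.id for ivx in list(universe)[: n // 2]}
        for k, ivx in enumerate(universe):
            if ivx.id in half and rng.random() < 0.4:
                entries.append(
                    (planted, iv(ivx.chrom, ivx.start, ivx.start + 10, f"q{k}"))
                )
            if rng.random() < 0.2:
                entries.append(
                    ("BG", iv(ivx.chrom, ivx.start + 20, ivx.start + 30, f"b{k}"))
                )
        return universe, TFCatalogue(entries), half

    def test_subset_equal_to_all_scores_zero(self, rng):
        universe, cat, _ = self._catalogued_universe(rng)
        profile = score_subset_vs_all(universe, universe, cat)
        assert all(s == 0.0 for s in profile.scores.values())

    def test_planted_half_ranks_planted_factor_first(self, rng):
        universe, cat, half = self._catalogued_universe(rng)
        subset = universe.subset(half, name="half")
        profile = score_subset_vs_all(subset, universe, cat)
        assert profile.top(1) == ["Q"]

    def test_foreign_subset_rejected(self, rng):
        universe, cat, _ = self._catalogued_universe(rng, n=100)
        foreign = PeakSet([iv("chr9", 0, 10, "zz")])
        with pytest.raises(ValueError, match="not contained"):
            score_subset_vs_all(foreign, universe, cat)

    def test_empty_subset_rejected(self, rng):
        universe, cat, _ = self._catalogued_universe(rng, n=100)
        with pytest.raises(ValueError, match="empty population"):
            score_subset_vs_all(PeakSet([]), universe, cat)


class TestPlantedRecovery:
    def test_threefold_enrichment_recovered(self):
        """Planted 3x co-occurrence recovered within the stated tolerance."""
        rng = np.random.default_rng(23)
        n = 6000
        rate = 0.1
        ivs_t, ivs_r, entries = [], [], []
        k = 0
        for i in range(n):
            s = 1000 * i
            ivs_t.append(iv("chr1", s, s + 500, f"t{i}"))
            ivs_r.append(iv("chr2", s, s + 500, f"r{i}"))
            if rng.random() < 3 * rate:
                k += 1
                entries.append(("Z", iv("chr1", s + 5, s + 20, f"z{k}")))
            if rng.random() < rate:
                k += 1
                entries.append(("Z", iv("chr2", s + 5, s + 20, f"z{k}")))
            for f in ("U", "V"):
                if rng.random() < rate:
                    k += 1
                    entries.append((f, iv("chr1", s + 30, s + 45, f"{f}{k}")))
                if rng.random() < rate:
                    k += 1
                    entries.append((f, iv("chr2", s + 60, s + 75, f"{f}{k}")))
        cat = TFCatalogue(entries)
        test = build_signature(PeakSet(ivs_t, name="test"), cat)
        ref = build_signature(PeakSet(ivs_r, name="ref"), cat)
        profile = score_vs_reference(test, ref)
        assert profile.top(1) == ["Z"]
        assert profile.scores["Z"] == pytest.approx(math.log2(3), abs=0.15)


class TestBinomialSE:
    def test_matches_delta_method(self):
        se = binomial_score_se(0.1, 1000)
        expected = math.sqrt(0.1 * 0.9 / 1000) / (0.1 * math.log(2))
        assert se == pytest.approx(expected)
        assert binomial_score_se(0.1, 1000, n_factors=4) == pytest.approx(
            expected / 2
        )

    def test_rejects_degenerate_rate(self):
        with pytest.raises(ValueError):
            binomial_score_se(0.0, 100)
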