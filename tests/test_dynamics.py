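"""Fold-change ranking, the FC=1.5 split, 1000-peak binning, group scores."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oracles import random_peakset
from remi import (
    DEFAULT_FACTOR_GROUPS,
    FactorGroup,
    GenomicInterval,
    PeakSet,
    TFCatalogue,
    bin_ranked_peaks,
    compute_fold_changes,
    group_score_series,
    split_by_fc,
    top_bottom_subsets,
)


def iv(chrom, start, end, id_):
    return GenomicInterval(chrom, start, end, id_)


def universe_of(n, width=500, gap=1000):
    return PeakSet(
        [iv("chr1", i * (width + gap), i * (width + gap) + width, f"e{i:05d}")
         for i in range(n)],
        name="u",
    )


def intensity_frame(values: dict[str, dict[int, float]]) -> pd.DataFrame:
    rows = [
        {"element_id": e, "timepoint_days": t, "intensity": v}
        for e, tv in values.items()
        for t, v in tv.items()
    ]
    return pd.DataFrame(rows)


class TestComputeFoldChanges:
    def test_ratio_arithmetic(self):
        u = universe_of(2)
        table = compute_fold_changes(
            u,
            intensity_frame({"e00000": {0: 20, 56: 30}, "e00001": {0: 10, 56: 10}}),
            0,
            56,
            normalize=None,
        )
        assert table.fc["e00000"] == pytest.approx(1.5)
        assert table.fc["e00001"] == pytest.approx(1.0)

    def test_missing_timepoints_excluded_and_reported(self):
        u = universe_of(3)
        table = compute_fold_changes(
            u,
            intensity_frame(
                {"e00000": {0: 20, 56: 30}, "e00001": {0: 10}, "e00002": {56: 5}}
            ),
            0,
            56,
        )
        assert set(table.fc.index) == {"e00000"}
        assert set(table.excluded) == {"e00001", "e00002"}

    def test_no_defined_element_is_an_error(self):
        u = universe_of(1)
        with pytest.raises(ValueError, match="no element"):
            compute_fold_changes(
                u, intensity_frame({"e00000": {0: 20}}), 0, 56
            )

    def test_ranking_matches_sort_oracle(self):
        rng = np.random.default_rng(5)
        n = 5000
        u = universe_of(n)
        ids = [f"e{i:05d}" for i in range(n)]
        i1 = rng.uniform(1, 100, n)
        i2 = rng.uniform(1, 100, n)
        frame = pd.concat(
            [
                pd.DataFrame(
                    {"element_id": ids, "timepoint_days": 0, "intensity": i1}
                ),
                pd.DataFrame(
                    {"element_id": ids, "timepoint_days": 56, "intensity": i2}
                ),
            ]
        )
        table = compute_fold_changes(u, frame, 0, 56, normalize=None)
        ratios = {e: b / a for e, a, b in zip(ids, i1, i2)}
        expected = sorted(ids, key=lambda e: (-ratios[e], e))
        assert list(table.fc.index) == expected
        for e in ids[:100]:
            assert table.fc[e] == pytest.approx(ratios[e])

    def test_total_normalisation_rescales_t2(self):
        u = universe_of(2)
        # t2 totals doubled; normalisation should bring both fc back to 1
        table = compute_fold_changes(
            u,
            intensity_frame(
                {"e00000": {0: 10, 56: 20}, "e00001": {0: 30, 56: 60}}
            ),
            0,
            56,
            normalize="total",
        )
        assert np.allclose(table.fc.values, 1.0)


class TestSplit:
    def make_table(self, fcs):
        n = len(fcs)
        u = universe_of(n)
        ids = [f"e{i:05d}" for i in range(n)]
        frame = pd.concat(
            [
                pd.DataFrame(
                    {"element_id": ids, "timepoint_days": 0, "intensity": 10.0}
                ),
                pd.DataFrame(
                    {
                        "element_id": ids,
                        "timepoint_days": 56,
                        "intensity": [10.0 * f for f in fcs],
                    }
                ),
            ]
        )
        return compute_fold_changes(u, frame, 0, 56, normalize=None)

    def test_closed_boundaries(self):
        table = self.make_table([1.5, 1.0, 1 / 1.5, 0.5, 2.0])
        split = split_by_fc(table)
        assert len(split.increased) == 2  # 1.5 itself is "increased"
        assert len(split.decreased) == 2  # 1/1.5 itself is "decreased"
        assert len(split.stable) == 1

    def test_threshold_validation(self):
        table = self.make_table([1.0])
        with pytest.raises(ValueError):
            split_by_fc(table, threshold=1.0)

    @pytest.mark.parametrize("threshold", [1.2, 1.5, 3.0])
    def test_partition_property(self, threshold):
        rng = np.random.default_rng(12)
        table = self.make_table(list(rng.uniform(0.2, 5.0, 400)))
        split = split_by_fc(table, threshold)
        all_ids = set(split.increased) | set(split.decreased) | set(split.stable)
        assert len(split.increased) + len(split.decreased) + len(split.stable) == len(
            table.fc
        )
        assert all_ids == set(table.fc.index)
        # brute-force recount
        fc = table.fc
        assert len(split.increased) == int((fc >= threshold).sum())
        assert len(split.decreased) == int((fc <= 1 / threshold).sum())


class TestBinning:
    def test_bin_sizes_and_partial_flag(self):
        table = TestSplit().make_table(list(np.linspace(0.5, 2.0, 2500)))
        bins = bin_ranked_peaks(table, bin_size=1000)
        assert [len(b.ids) for b in bins] == [1000, 1000, 500]
        assert [b.partial for b in bins] == [False, False, True]

    def test_single_small_bin(self):
        table = TestSplit().make_table(list(np.linspace(0.5, 2.0, 800)))
        bins = bin_ranked_peaks(table, bin_size=1000)
        assert len(bins) == 1 and len(bins[0].ids) == 800 and bins[0].partial

    def test_concatenation_reproduces_rank_order(self):
        table = TestSplit().make_table(list(np.linspace(0.5, 2.0, 2500)))
        bins = bin_ranked_peaks(table, bin_size=700)
        concat = tuple(i for b in bins for i in b.ids)
        assert concat == table.ranked_ids()


class TestGroupScores:
    def small_catalogue(self, universe, rng, rate=0.3):
        factors = sorted({f for g in DEFAULT_FACTOR_GROUPS for f in g.factors})
        entries = []
        k = 0
        for f in factors:
            for ivx in universe:
                if rng.random() < rate:
                    k += 1
                    entries.append(
                        (f, iv(ivx.chrom, ivx.start, ivx.start + 10, f"s{k}"))
                    )
        return TFCatalogue(entries)

    def test_single_bin_scores_zero(self, rng):
        table = TestSplit().make_table(list(np.linspace(0.5, 2.0, 300)))
        cat = self.small_catalogue(table.universe, rng)
        bins = bin_ranked_peaks(table, bin_size=1000)  # one bin of 300
        series = group_score_series(bins, table.universe, cat)
        assert np.allclose(series.scores.to_numpy(), 0.0)

    def test_missing_group_factor_is_named(self, rng):
        table = TestSplit().make_table(list(np.linspace(0.5, 2.0, 50)))
        cat = self.small_catalogue(table.universe, rng)
        bad = (FactorGroup("X", frozenset({"NOSUCH"})),)
        with pytest.raises(ValueError, match="NOSUCH"):
            group_score_series(
                bin_ranked_peaks(table, 25), table.universe, cat, groups=bad
            )


class TestTopBottom:
    def test_toy_enumeration(self):
        fcs = [2.0, 2.0, 1.0, 1.0, 0.4, 0.4]
        table = TestSplit().make_table(fcs)
        split = split_by_fc(table)
        promoters = {"e00000", "e00004"}
        top_p, bot_p = top_bottom_subsets(table, split, "promoter", promoters)
        top_n, bot_n = top_bottom_subsets(table, split, "non-promoter", promoters)
        assert set(top_p.ids()) == {"e00000"}
        assert set(bot_p.ids()) == {"e00004"}
        assert set(top_n.ids()) == {"e00001"}
        assert set(bot_n.ids()) == {"e00005"}

    def test_all_stable_gives_empty_subsets(self):
        table = TestSplit().make_table([1.0, 1.1, 0.95])
        split = split_by_fc(table)
        top, bot = top_bottom_subsets(table, split, "promoter", set())
        assert len(top) == 0 and len(bot) == 0

    def test_matches_brute_force_intersection(self, rng):
        fcs = list(rng.uniform(0.3, 3.0, 200))
        table = TestSplit().make_table(fcs)
        split = split_by_fc(table)
        promoters = {f"e{i:05d}" for i in range(200) if rng.random() < 0.5}
        top, bot = top_bottom_subsets(table, split, "promoter", promoters)
        assert set(top.ids()) == set(split.increased) & promoters
        assert set(bot.ids()) == set(split.decreased) & promoters
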