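import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_methylome, uniform_region_sites
from dmrscan.windows import (
    WindowParams,
    generate_windows,
    min_level_guard,
    passes_filters,
    scan_chromosome,
    summarize_window,
)
from oracles import enumerate_windows, window_summary_naive


class TestGenerateWindows:
    def test_stated_convention(self):
        w = generate_windows(1200, WindowParams())
        assert w.tolist() == [[1, 1000], [101, 1100], [201, 1200]]

    def test_short_chromosome_is_one_clipped_window(self):
        assert generate_windows(500, WindowParams()).tolist() == [[1, 500]]

    def test_closed_form_count(self):
        w = generate_windows(10_000, WindowParams())
        assert len(w) == (10_000 - 1000) // 100 + 1 == 91
        assert w[-1].tolist() == [9001, 10_000]

    @given(
        length=st.integers(1, 5000),
        window=st.integers(1, 1500),
        step=st.integers(1, 1500),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_and_covers_every_base(self, length, window, step):
        if step > window:
            window, step = step, window
        params = WindowParams(window_size=window, step_size=step, min_sites=1)
        got = [tuple(x) for x in generate_windows(length, params)]
        assert got == enumerate_windows(length, window, step)
        covered = np.zeros(length + 1, dtype=bool)
        for s, e in got:
            covered[s : e + 1] = True
        assert covered[1:].all()

    def test_interior_base_multiplicity(self):
        # when window/step is integral every interior base sits in w/s windows
        params = WindowParams(window_size=1000, step_size=100)
        counts = np.zeros(10_001, dtype=int)
        for s, e in generate_windows(10_000, params):
            counts[s : e + 1] += 1
        assert (counts[1000:9001] == 10).all()


class TestMinLevelGuard:
    def test_floor_rules(self):
        assert np.allclose(min_level_guard([0.5, 0.0]), [0.5, 0.001])
        assert np.allclose(min_level_guard([0.0, 0.0]), [0.001, 0.001])
        assert np.allclose(min_level_guard([0.3, 0.2]), [0.3, 0.2])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            min_level_guard([1.2, 0.1])


class TestSummarizeWindow:
    def test_unweighted_mean_of_per_site_ratios(self):
        ms = make_methylome({
            "a": [("chr1", 100, 4, 0), ("chr1", 200, 0, 4)],
            "b": [("chr1", 100, 4, 0), ("chr1", 200, 4, 0)],
        })
        stats = summarize_window("chr1", 1, 1000, ms, WindowParams())
        assert stats.mean_level[0] == pytest.approx(0.5)

    def test_identical_samples_have_no_effect(self):
        sites = [("chr1", p, 6, 4) for p in range(100, 600, 100)]
        ms = make_methylome({"a": sites, "b": sites})
        stats = summarize_window("chr1", 1, 1000, ms, WindowParams())
        assert stats.diff == pytest.approx(0.0)
        assert stats.fold_change == pytest.approx(1.0)

    def test_hand_checked_arithmetic(self):
        ms = make_methylome({
            "a": [("chr1", 100, 9, 1), ("chr1", 200, 8, 2), ("chr1", 300, 7, 3)],
            "b": [("chr1", 100, 2, 8), ("chr1", 200, 3, 7), ("chr1", 300, 1, 9)],
        })
        stats = summarize_window("chr1", 1, 1000, ms, WindowParams())
        assert stats.mean_level[0] == pytest.approx(0.8)
        assert stats.mean_level[1] == pytest.approx(0.2)
        assert stats.diff == pytest.approx(0.6)
        assert stats.fold_change == pytest.approx(4.0)
        assert stats.n_sites == 3

    def test_empty_window_is_flagged(self):
        ms = make_methylome({"a": [("chr1", 5000, 9, 1)], "b": [("chr1", 5000, 1, 9)]})
        stats = summarize_window("chr1", 1, 1000, ms, WindowParams())
        assert stats.empty
        ok, reason = passes_filters(stats, WindowParams())
        assert not ok and reason == "min_sites"

    def test_depth_criterion_applies_in_every_sample(self):
        ms = make_methylome({
            "a": [("chr1", 100, 4, 0), ("chr1", 200, 4, 0)],
            "b": [("chr1", 100, 2, 1), ("chr1", 200, 4, 0)],  # pos 100 depth 3 < 4
        })
        stats = summarize_window("chr1", 1, 1000, ms, WindowParams())
        assert list(stats.site_positions) == [200]


class TestPassesFilters:
    @pytest.mark.parametrize(
        "n_sites,fold,diff,expect",
        [
            (5, 1.5, 0.2, (True, None)),  # thresholds are inclusive
            (4, 4.0, 0.6, (False, "min_sites")),
            (5, 1.4, 0.6, (False, "min_fold")),
            (5, 4.0, 0.15, (False, "min_diff")),
        ],
    )
    def test_threshold_rules(self, n_sites, fold, diff, expect):
        from dmrscan.windows import WindowStats

        stats = WindowStats("chr1", 1, 1000, np.arange(n_sites), n_sites,
                            np.array([0.5, 0.5]), fold, diff)
        assert passes_filters(stats, WindowParams()) == expect

    def test_strict_mode_excludes_boundary(self):
        from dmrscan.windows import WindowStats

        stats = WindowStats("chr1", 1, 1000, np.arange(5), 5, np.array([0.5, 0.5]), 1.5, 0.2)
        assert passes_filters(stats, WindowParams(strict=True))[0] is False

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        sites = {
            s: [("chr1", 50 * i + 1, int(m), int(u)) for i, (m, u) in
                enumerate(zip(rng.integers(0, 12, 40), rng.integers(1, 12, 40)))]
            for s in ("a", "b")
        }
        sites["b"] = [("chr1", p, u, m) for (_, p, m, u) in sites["a"]]
        ms = make_methylome(sites)
        loose = WindowParams(min_depth=1, min_sites=2, min_fold=1.0, min_diff=0.0)
        tight = WindowParams(min_depth=4, min_sites=5, min_fold=1.5, min_diff=0.2)
        loose_pass = {i for i, w in enumerate(generate_windows(2000, loose))
                      if passes_filters(summarize_window("chr1", *w, ms, loose), loose)[0]}
        tight_pass = {i for i, w in enumerate(generate_windows(2000, tight))
                      if passes_filters(summarize_window("chr1", *w, ms, tight), tight)[0]}
        assert tight_pass <= loose_pass


class TestScanChromosome:
    def test_agrees_with_per_window_summary(self):
        rng = np.random.default_rng(11)
        n = 120
        positions = np.sort(rng.choice(np.arange(1, 6000), size=n, replace=False))
        recs = {}
        for s in ("a", "b", "c"):
            depth = rng.integers(0, 40, n)
            meth = rng.binomial(depth, rng.random(n))
            recs[s] = [("chr1", int(p), int(m), int(d - m))
                       for p, m, d in zip(positions, meth, depth)]
        ms = make_methylome(recs, chrom_sizes={"chr1": 6000})
        params = WindowParams()
        table = scan_chromosome("chr1", ms, params)
        naive = {s: {p: (m, u) for _, p, m, u in recs[s]} for s in recs}
        for i in range(len(table.starts)):
            stats = summarize_window("chr1", int(table.starts[i]), int(table.ends[i]), ms, params)
            assert table.n_sites[i] == stats.n_sites
            if stats.n_sites:
                np.testing.assert_allclose(table.mean_level[:, i], stats.mean_level, atol=1e-12)
                assert table.fold_change[i] == pytest.approx(stats.fold_change)
                assert table.diff[i] == pytest.approx(stats.diff)
            assert table.passed[i] == passes_filters(stats, params)[0]
            admitted, means = window_summary_naive(
                naive, int(table.starts[i]), int(table.ends[i]), params.min_depth
            )
            assert stats.n_sites == len(admitted)
            if admitted:
                np.testing.assert_allclose(stats.mean_level, means, atol=1e-12)


def test_window_params_validation():
    with pytest.raises(ValueError):
        WindowParams(window_size=500, step_size=600)
    with pytest.raises(ValueError):
        WindowParams(min_fold=0.5)
    with pytest.raises(ValueError):
        WindowParams(min_diff=1.5)
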