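"""Window statistics, run comparison, density classes, PMDs, calibration."""

import numpy as np
import pytest

from bsartifact.align import TrimRule
from bsartifact.calls import CytosineCallTable, extract_calls_truth
from bsartifact.genome import (
    CPG,
    Window,
    index_cytosines,
    synthetic_genome,
    tile_windows,
)
from bsartifact.regions import (
    WindowStat,
    calibrate_mixtures,
    call_pmds,
    compare_runs,
    density_classes,
    window_levels,
)
from bsartifact.simulate import (
    ArtifactModel,
    MethylomeSpec,
    SimulationConfig,
    realize_methylome,
    simulate_library,
)
from oracles import brute_pmds


def _set_level(table, mask, meth, unmeth):
    table.counts[mask, 0, 0] = meth
    table.counts[mask, 0, 1] = unmeth


@pytest.fixture(scope="module")
def pmd_genome():
    g = synthetic_genome(140_000, seed=77, name="p")
    return g, index_cytosines(g)


def _domain_table(idx, domains, default=(4, 1)):
    """Cover every CpG; (meth, unmeth) per CpG by domain, default 80%."""
    t = CytosineCallTable(idx)
    cpg = idx.context == CPG
    _set_level(t, cpg, *default)
    for start, end, counts in domains:
        m = cpg & (idx.pos >= start) & (idx.pos < end)
        _set_level(t, m, *counts)
    return t


class TestWindowLevels:
    def test_all_methylated_windows_at_100(self, pmd_genome):
        g, idx = pmd_genome
        t = _domain_table(idx, [], default=(3, 0))
        stats = window_levels(t, tile_windows(g, 10_000))
        assert all(s.level == 100.0 for s in stats)
        assert all(s.n_covered == s.n_cpg for s in stats)

    def test_uncovered_window_is_undefined_not_zero(self, pmd_genome):
        g, idx = pmd_genome
        t = _domain_table(idx, [(0, 10_000, (0, 0))])
        stats = window_levels(t, tile_windows(g, 10_000))
        assert stats[0].level is None and stats[0].n_covered == 0
        assert stats[1].level == pytest.approx(80.0)

    def test_constructed_counts_match_hand_pooled_ratio(self, pmd_genome):
        g, idx = pmd_genome
        t = _domain_table(idx, [(0, 5_000, (1, 0)), (5_000, 10_000, (0, 1))])
        stats = window_levels(t, [Window("p", 0, 10_000)])
        cpg = idx.context == CPG
        n_first = int((cpg & (idx.pos < 5_000)).sum())
        n_second = int((cpg & (idx.pos >= 5_000) & (idx.pos < 10_000)).sum())
        assert stats[0].level == pytest.approx(100 * n_first / (n_first + n_second))


class TestDensityClasses:
    def _stats(self, counts):
        return [WindowStat(Window("c", i * 10, (i + 1) * 10), c, c, 50.0)
                for i, c in enumerate(counts)]

    def test_nine_distinct_counts_one_per_class(self):
        cls = density_classes(self._stats([5, 10, 15, 20, 25, 30, 35, 40, 45]), k=9)
        assert sorted(cls) == list(range(9))

    def test_ties_collapse_to_one_class(self):
        cls = density_classes(self._stats([7] * 12), k=9)
        assert set(cls) == {0}

    def test_ninety_windows_ten_per_class(self):
        cls = density_classes(self._stats(list(range(90))), k=9)
        assert np.bincount(cls).tolist() == [10] * 9

    def test_rejects_bad_k(self):
        with pytest.raises(ValueError):
            density_classes(self._stats([1, 2, 3]), k=0)


class TestCompareRuns:
    def _stats(self, levels, n_cpg=None):
        n_cpg = n_cpg or list(range(10, 10 + len(levels)))
        return [
            WindowStat(Window("c", i * 10, (i + 1) * 10), n, n, lv)
            for i, (lv, n) in enumerate(zip(levels, n_cpg))
        ]

    def test_self_comparison_is_identity(self):
        a = self._stats([10.0, 50.0, 80.0, 30.0, 60.0, 20.0, 70.0, 40.0, 90.0])
        cmp = compare_runs(a, a)
        assert np.allclose(cmp.table["delta"], 0)
        assert (cmp.slope, cmp.intercept, cmp.correlation) == (1.0, 0.0, 1.0)

    def test_affine_shift(self):
        b = self._stats([10.0, 50.0, 80.0, 30.0, 60.0, 20.0, 70.0, 40.0, 90.0])
        a = self._stats([lv + 5 for lv in (10.0, 50.0, 80.0, 30.0, 60.0, 20.0,
                                           70.0, 40.0, 90.0)])
        cmp = compare_runs(a, b)
        assert cmp.slope == pytest.approx(1.0)
        assert cmp.intercept == pytest.approx(5.0)
        assert np.allclose(cmp.table["delta"], 5.0)

    def test_undefined_windows_dropped_from_intersection(self):
        a = self._stats([10.0, None, 30.0])
        b = self._stats([12.0, 20.0, None])
        cmp = compare_runs(a, b)
        assert len(cmp.table) == 1

    def test_mismatched_window_sets_rejected(self):
        a = self._stats([10.0, 20.0])
        b = [WindowStat(Window("other", 0, 10), 5, 5, 10.0),
             WindowStat(Window("other", 10, 20), 5, 5, 20.0)]
        with pytest.raises(ValueError):
            compare_runs(a, b)

    def test_artifact_bias_shows_as_mean_delta(self, lambda_genome, lambda_index):
        """G undercall at rate q on R1 shifts window levels by about
        -100*m*q/2 points when R1 and R2 calls are pooled (R2 unaffected)."""
        m_level, q = 0.6, 0.12
        meth = realize_methylome(lambda_index, MethylomeSpec.uniform(m_level))
        cfg = SimulationConfig(n_fragments=2500, seed=41)
        clean = simulate_library(lambda_genome, meth, cfg)
        art = ArtifactModel(g_to_a_rate=q)
        rng = np.random.default_rng(42)
        from bsartifact.simulate import apply_artifact

        arted = [apply_artifact(r, art, rng) for r in clean]
        windows = tile_windows(lambda_genome, 5_000)
        sa = window_levels(extract_calls_truth(arted, lambda_index, TrimRule()), windows)
        sb = window_levels(extract_calls_truth(clean, lambda_index, TrimRule()), windows)
        cmp = compare_runs(sa, sb)
        expected = -100 * m_level * q / 2  # artifact hits the R1 half of calls
        assert cmp.table["delta"].mean() == pytest.approx(expected, abs=1.5)
        assert cmp.slope == pytest.approx(1.0, abs=0.15)


class TestCallPMDs:
    def test_high_methylation_genome_has_no_pmds(self, pmd_genome):
        g, idx = pmd_genome
        assert call_pmds(_domain_table(idx, []), g) == []

    def test_twelve_windows_give_one_120kb_pmd(self, pmd_genome):
        g, idx = pmd_genome
        t = _domain_table(idx, [(10_000, 130_000, (1, 1))])  # 50% block
        pmds = call_pmds(t, g)
        assert len(pmds) == 1
        p = pmds[0]
        assert (p.start, p.end, p.length) == (10_000, 130_000, 120_000)
        assert p.mean_level == pytest.approx(50.0)

    def test_ten_windows_is_not_longer_than_100kb(self, pmd_genome):
        g, idx = pmd_genome
        t = _domain_table(idx, [(10_000, 110_000, (1, 1))])  # exactly 100 kb
        assert call_pmds(t, g) == []

    def test_ineligible_window_breaks_contiguity(self, pmd_genome):
        g, idx = pmd_genome
        t = _domain_table(idx, [(0, 140_000, (1, 1))])
        # kill coverage in one middle window: each side is < 100 kb
        mid = (idx.pos >= 60_000) & (idx.pos < 70_000)
        t.counts[mid] = 0
        assert call_pmds(t, g) == []

    def test_output_satisfies_printed_thresholds_and_matches_bruteforce(self):
        """Random call tables: every PMD is >100 kb with level <70%, and the
        caller agrees with an independent window-scan oracle."""
        g = synthetic_genome(300_000, seed=5, name="r")
        idx = index_cytosines(g)
        rng = np.random.default_rng(6)
        for trial in range(5):
            t = CytosineCallTable(idx)
            cpg = np.nonzero(idx.context == CPG)[0]
            covered = rng.random(len(cpg)) < 0.6
            lv = rng.random(len(cpg))
            t.counts[cpg[covered], 0, 0] = np.maximum(
                0, rng.binomial(4, lv[covered])
            )
            t.counts[cpg[covered], 0, 1] = 4 - t.counts[cpg[covered], 0, 0]
            pmds = call_pmds(t, g)
            for p in pmds:
                assert p.length > 100_000
                assert p.mean_level < 70.0
            stats = window_levels(t, tile_windows(g, 10_000))
            rows = [
                (s.window.chrom, s.window.start, s.window.end, s.n_covered, s.level)
                for s in stats
            ]
            assert [(p.chrom, p.start, p.end) for p in pmds] == brute_pmds(rows)


class TestCalibrateMixtures:
    def _point(self, lambda_genome, lambda_index, pi, seed, artifact=None):
        meth = realize_methylome(lambda_index, MethylomeSpec.mixture(pi))
        cfg = SimulationConfig(n_fragments=1500, seed=seed)
        reads = simulate_library(lambda_genome, meth, cfg, artifact=artifact)
        return extract_calls_truth(reads, lambda_index, TrimRule())

    def test_clean_recovery_at_44_percent(self, lambda_genome, lambda_index):
        t = self._point(lambda_genome, lambda_index, 0.44, seed=51)
        (pt,) = calibrate_mixtures([(44.0, t)])
        sd = 100 * np.sqrt(0.44 * 0.56 / 1500)  # molecule-level binomial
        assert abs(pt.diff_r1) < 4 * sd
        assert abs(pt.diff_r2) < 4 * sd
        assert abs(pt.r1_r2_gap) < 4 * sd

    def test_g_undercall_biases_r1_by_pi_q(self, lambda_genome, lambda_index):
        pi, q = 0.44, 0.1
        art = ArtifactModel(g_to_a_rate=q)
        t = self._point(lambda_genome, lambda_index, pi, seed=52, artifact=art)
        (pt,) = calibrate_mixtures([(44.0, t)])
        sd = 100 * np.sqrt(pi * (1 - pi) / 1500)
        assert pt.diff_r1 == pytest.approx(-100 * pi * q, abs=4 * sd)
        assert pt.diff_r2 == pytest.approx(0.0, abs=4 * sd)

    def test_zero_mixture_observes_zero(self, lambda_genome, lambda_index):
        t = self._point(lambda_genome, lambda_index, 0.0, seed=53)
        (pt,) = calibrate_mixtures([(0.0, t)])
        assert pt.observed_r1 == 0.0 and pt.observed_r2 == 0.0
        assert pt.diff_r1 == 0.0 and pt.r1_r2_gap == 0.0

    def test_empty_runs_rejected(self):
        with pytest.raises(ValueError):
            calibrate_mixtures([])
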