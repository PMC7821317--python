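import numpy as np
import pandas as pd
import pytest

from opsel.condition import StressScenario
from opsel.reproduction import ReproductionParams
from opsel.simulate import run_sweep, simulate_replicate, summarize_sweep


def brute_force_replicate(scenario, g_m, n_per_sex, seed):
    """Independent re-evaluation of one replicate from the written-out
    equations: Eggs = c_f, sperm never limiting, males split total female
    fecundity by c^g / (c^g + c'^g).  Shares the seed-tree layout with the
    package (spawn order: females, males, partition) but none of its
    model code.
    """
    ss = np.random.SeedSequence(seed)
    f_ss, m_ss, part_ss = ss.spawn(3)

    def draw(n, sigma, s):
        r = np.random.default_rng(s)
        c = r.normal(1.0, sigma, n) if sigma > 0 else np.ones(n)
        return np.maximum(c, 0.0)

    cf = draw(n_per_sex, scenario.sigma_f, f_ss)
    cm = draw(n_per_sex, scenario.sigma_m, m_ss)
    r = np.random.default_rng(part_ss)
    fo, mo = r.permutation(n_per_sex), r.permutation(n_per_sex)
    wf, wm = np.empty(n_per_sex), np.empty(n_per_sex)
    for k in range(n_per_sex // 2):
        f1, f2 = fo[2 * k], fo[2 * k + 1]
        m1, m2 = mo[2 * k], mo[2 * k + 1]
        eggs1, eggs2 = cf[f1], cf[f2]
        total = eggs1 + eggs2
        share1 = cm[m1] ** g_m / (cm[m1] ** g_m + cm[m2] ** g_m)
        wf[f1], wf[f2] = eggs1, eggs2
        wm[m1], wm[m2] = total * share1, total * (1.0 - share1)

    def crow_I(w):
        return w.var(ddof=1) / w.mean() ** 2

    return crow_I(wf), crow_I(wm)


class TestSimulateReplicate:
    def test_zero_stress_gives_zero_opportunity(self):
        scen = StressScenario("none", 0.0, 0.0)
        assert simulate_replicate(scen, ReproductionParams(), 100, 3) == (0.0, 0.0)

    def test_female_stress_hits_analytic_limit_and_spills_to_males(self):
        """I_f -> sigma_f^2; males inherit variance by sharing variable
        female fecundity, so I_m > 0 even with sigma_m = 0."""
        scen = StressScenario("female_only", 0.2, 0.0)
        I_f, I_m = simulate_replicate(scen, ReproductionParams(), 100_000, 17)
        assert I_f == pytest.approx(0.04, abs=0.003)
        assert I_m > 0.005

    def test_male_only_stress_leaves_female_I_at_exact_zero(self):
        scen = StressScenario("male_only", 0.0, 0.2)
        I_f, I_m = simulate_replicate(scen, ReproductionParams(), 1000, 23)
        assert I_f == 0.0
        assert I_m > 0.0

    def test_determinism(self):
        scen = StressScenario("both", 0.3, 0.3)
        a = simulate_replicate(scen, ReproductionParams(), 200, 5)
        b = simulate_replicate(scen, ReproductionParams(), 200, 5)
        assert a == b

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize(
        "scenario",
        [
            StressScenario("both", 0.25, 0.25),
            StressScenario("female_only", 0.4, 0.05),
            StressScenario("male_only", 0.05, 0.4),
        ],
    )
    def test_matches_brute_force_oracle_at_two_groups(self, scenario, seed):
        """n_per_sex = 4 (two mating groups): package output equals an
        independent brute-force evaluation of the model equations."""
        got = simulate_replicate(scenario, ReproductionParams(g_m=2), 4, seed)
        want = brute_force_replicate(scenario, 2.0, 4, seed)
        assert got[0] == pytest.approx(want[0], abs=1e-12)
        assert got[1] == pytest.approx(want[1], abs=1e-12)

    def test_odd_n_rejected(self):
        with pytest.raises(ValueError):
            simulate_replicate(StressScenario("none", 0, 0), ReproductionParams(), 5, 0)


class TestRunSweep:
    def test_single_cell_reproducible(self):
        a = run_sweep(["both"], [0.1], replicates=1, n_per_sex=100, seed=9)
        b = run_sweep(["both"], [0.1], replicates=1, n_per_sex=100, seed=9)
        assert len(a) == 1
        assert a[0].mean_I_f == b[0].mean_I_f
        assert a[0].mean_log_ratio == b[0].mean_log_ratio

    def test_equal_stress_is_male_biased_with_strong_male_competition(self):
        res = run_sweep(
            ["both"], [0.1, 0.3], replicates=20, n_per_sex=300, seed=21
        )
        assert all(r.mean_log_ratio > 0 for r in res)

    def test_female_only_sweep_drives_ratio_toward_females(self):
        res = run_sweep(
            ["female_only"], [0.1, 0.2, 0.3, 0.4], replicates=20,
            n_per_sex=300, seed=8,
        )
        ratios = [r.mean_log_ratio for r in res]
        assert ratios == sorted(ratios, reverse=True)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            run_sweep(["both"], [], replicates=1)


class TestSummarizeSweep:
    def test_tidy_shape_and_round_trip(self, tmp_path):
        res = run_sweep(
            ["both", "male_only"], [0.1, 0.2], replicates=3, n_per_sex=50, seed=2
        )
        df = summarize_sweep(res)
        assert list(df.columns) == ["scenario", "stress", "rep", "I_f", "I_m", "log_ratio"]
        assert len(df) == 2 * 2 * 3
        path = tmp_path / "sweep.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t")
        pd.testing.assert_frame_equal(back, df, check_exact=False)

    def test_means_match_results(self):
        res = run_sweep(["both"], [0.2], replicates=5, n_per_sex=50, seed=4)
        df = summarize_sweep(res)
        assert df["I_f"].mean() == pytest.approx(res[0].mean_I_f)
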