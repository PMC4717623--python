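"""Paired tests, fold changes, screening design, genotype means."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import arenatrack as at
from arenatrack.stats import (
    AlphaDesign,
    assumption_checks,
    fit_genotype_means,
    fold_change,
    make_alpha_design,
    paired_t,
    paired_test,
    wilcoxon_signed_rank,
)


def exhaustive_wilcoxon_p(diffs):
    """Full 2^n sign-flip enumeration oracle (midranks for ties)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    eps = 1e-9
    p_le = (ws <= w_obs + eps).mean()
    p_ge = (ws >= w_obs - eps).mean()
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_nine_unanimous_differences(self):
        w, p = wilcoxon_signed_rank(np.full(9, 2.5), mode="exact")
        assert w == 45.0
        assert p == pytest.approx(2 / 2**9)
        assert round(p, 3) == 0.004

    def test_symmetric_pairs_p_one(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        _, p = wilcoxon_signed_rank(d, mode="exact")
        assert p == 1.0

    @pytest.mark.parametrize("n", range(2, 13))
    def test_exact_matches_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        d = np.round(rng.normal(0.3, 1.0, n), 1)  # rounding creates ties
        d = np.where(d == 0, 0.1, d)
        _, p = wilcoxon_signed_rank(d, mode="exact")
        assert p == pytest.approx(exhaustive_wilcoxon_p(d), abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(42)
        d = rng.normal(0.5, 1.0, 12)
        _, p = wilcoxon_signed_rank(d, mode="exact")
        assert p == pytest.approx(sps.wilcoxon(d, mode="exact").pvalue, abs=1e-12)

    def test_normal_approx_close_to_exact_for_moderate_n(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.4, 1.0, 20)
        _, p_exact = wilcoxon_signed_rank(d, mode="exact")
        _, p_norm = wilcoxon_signed_rank(d, mode="normal_approx")
        assert p_norm == pytest.approx(p_exact, abs=0.03)

    def test_zeros_dropped(self):
        _, p = wilcoxon_signed_rank(np.array([0.0, 0.0, 1.0, 2.0, 3.0]), mode="exact")
        assert p == pytest.approx(2 / 2**3)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.zeros(5))

    def test_pairs_interface(self):
        pairs = np.column_stack([np.arange(9) + 1.0, np.arange(9.0)])
        _, p = wilcoxon_signed_rank(pairs, mode="exact")
        assert p == pytest.approx(2 / 2**9)


class TestPairedT:
    def test_constant_differences_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            paired_t(np.full(6, 3.0))

    def test_antisymmetric_zero_mean(self):
        t, df, p = paired_t(np.array([1.0, -1.0, 2.0, -2.0]))
        assert t == 0.0 and p == pytest.approx(1.0) and df == 3

    def test_hand_computed_six_values(self):
        d = np.array([1.0, 2.0, 0.0, 3.0, -1.0, 1.0])
        # mean 1, sd sqrt(2), n 6 -> t = 1 / (sqrt(2)/sqrt(6)) = sqrt(3)
        t, df, p = paired_t(d)
        assert t == pytest.approx(np.sqrt(3.0))
        assert df == 5
        assert p == pytest.approx(2 * sps.t.sf(np.sqrt(3.0), 5))

    def test_matches_scipy_on_pairs(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(10, 2, 15), rng.normal(9, 2, 15)
        t, df, p = paired_t(np.column_stack([a, b]))
        ref = sps.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)


class TestAssumptionChecksAndRouting:
    def test_identical_groups_levene_zero(self):
        g = list(np.arange(10.0))
        out = assumption_checks([g, g])
        assert out["levene_p"] == pytest.approx(1.0)

    def test_bimodal_sample_rejected_by_shapiro(self):
        rng = np.random.default_rng(3)
        g = np.concatenate([rng.normal(-8, 0.5, 25), rng.normal(8, 0.5, 25)])
        assert assumption_checks([g])["shapiro_p"][0] < 0.05

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            assumption_checks([[1.0, 2.0]])

    def test_auto_routes_skewed_to_wilcoxon(self):
        rng = np.random.default_rng(4)
        d = rng.lognormal(0, 1.5, 40)
        assert paired_test(d)["test"] == "wilcoxon"

    def test_auto_routes_normal_to_t(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.5, 1, 40)
        assert paired_test(d)["test"] == "paired_t"


class TestFoldChange:
    @pytest.mark.parametrize(
        "a,b,raw,rounded",
        [(837, 25, 33.48, 33), (8.7, 2.2, 3.95, 4), (45.6, 8.5, 5.36, 5), (7.0, 7.0, 1.0, 1)],
    )
    def test_printed_fold_changes(self, a, b, raw, rounded):
        r, k = fold_change(a, b)
        assert r == pytest.approx(raw, abs=0.01)
        assert k == rounded

    def test_order_invariant(self):
        assert fold_change(2.0, 10.0) == fold_change(10.0, 2.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fold_change(5.0, 0.0)


class TestAlphaDesign:
    def test_full_screen_dimensions(self):
        d = make_alpha_design(360, 5, 18, 20, seed=0)
        a = d.allocation
        assert len(a) == 360 * 5
        counts = a.groupby("accession").size()
        assert (counts == 5).all()
        per_round = a.groupby(["round", "accession"]).size()
        assert (per_round == 1).all()

    def test_minimal_case(self):
        d = make_alpha_design(4, 1, 2, 2, seed=1)
        assert sorted(d.allocation["accession"]) == [0, 1, 2, 3]
        assert (d.allocation.groupby("block").size() == 2).all()

    def test_seed_determinism(self):
        a = make_alpha_design(40, 2, 4, 10, seed=7).allocation
        b = make_alpha_design(40, 2, 4, 10, seed=7).allocation
        c = make_alpha_design(40, 2, 4, 10, seed=8).allocation
        assert a.equals(b)
        assert not a.equals(c)

    def test_reference_side_alternates_by_plate_row(self):
        d = make_alpha_design(360, 1, 18, 20, seed=0)
        g = d.allocation[d.allocation.block == 0]
        sides = g.sort_values("position")["reference_side"].tolist()
        assert sides[:5] == ["left"] * 5 and sides[5:10] == ["right"] * 5

    def test_invariants_hold_across_seeds(self):
        for seed in range(5):
            make_alpha_design(60, 3, 6, 10, seed=seed).validate()

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError):
            make_alpha_design(361, 5, 18, 20, seed=0)


def _simulate_screen(n_geno, n_rounds, blocks, block_size, sd_block, sd_e, seed,
                     round_effects=None):
    rng = np.random.default_rng(seed)
    design = make_alpha_design(n_geno, n_rounds, blocks, block_size, seed=seed)
    g_eff = rng.normal(0, 1, n_geno)
    r_eff = rng.normal(0, 0.5, n_rounds) if round_effects is None else np.asarray(round_effects)
    obs = design.allocation.rename(columns={"accession": "genotype"}).copy()
    b_eff = rng.normal(0, sd_block, (n_rounds, blocks))
    obs["value"] = (
        10.0
        + g_eff[obs.genotype]
        + r_eff[obs["round"]]
        + b_eff[obs["round"], obs.block]
        + rng.normal(0, sd_e, len(obs))
    )
    return obs[["genotype", "round", "block", "value"]], g_eff


class TestGenotypeMeans:
    def test_zero_block_variance_recovers_raw_means(self):
        obs, _ = _simulate_screen(12, 3, 3, 4, sd_block=0.0, sd_e=1e-6, seed=0)
        res = fit_genotype_means(obs)
        raw = obs.groupby("genotype")["value"].mean()
        est = res.means.set_index("genotype")["blue"]
        assert np.abs(est - raw).max() < 1e-3
        assert res.sigma2_block < 1e-3

    def test_parameter_recovery_full_screen(self):
        obs, g_eff = _simulate_screen(360, 5, 18, 20, sd_block=1.0, sd_e=1.0, seed=11)
        res = fit_genotype_means(obs)
        est = res.means.sort_values("genotype")["blue"].to_numpy()
        corr = np.corrcoef(est, g_eff)[0, 1]
        slope = np.polyfit(g_eff, est, 1)[0]
        assert corr >= 0.9
        assert 0.85 <= slope <= 1.05

    def test_round_effect_cancels_in_genotype_contrast(self):
        # 2 genotypes, complete balanced 2-round design, known round shift
        rows = []
        for r, shift in enumerate((0.0, 5.0)):
            for g, geff in enumerate((0.0, 2.0)):
                for rep in range(4):
                    rows.append(dict(genotype=g, round=r, block=0, value=1.0 + geff + shift))
        obs = pd.DataFrame(rows)
        # add tiny noise so the residual variance is positive
        obs["value"] += np.random.default_rng(0).normal(0, 1e-6, len(obs))
        res = fit_genotype_means(obs)
        m = res.means.set_index("genotype")["blue"]
        assert m[1] - m[0] == pytest.approx(2.0, abs=1e-4)

    def test_matches_statsmodels_mixedlm(self):
        """Independent cross-check: REML variance components and genotype
        means agree with statsmodels MixedLM on a mid-sized screen."""
        smf = pytest.importorskip("statsmodels.formula.api")
        obs, _ = _simulate_screen(20, 4, 4, 5, sd_block=1.0, sd_e=0.7, seed=2)
        mine = fit_genotype_means(obs)
        df = obs.copy()
        df["grp"] = df["round"].astype(str) + ":" + df.block.astype(str)
        m = smf.mixedlm("value ~ C(round) + C(genotype)", df, groups=df.grp).fit(reml=True)
        assert mine.sigma2_e == pytest.approx(m.scale, rel=0.05)
        assert mine.sigma2_block == pytest.approx(float(m.cov_re.iloc[0, 0]), rel=0.1, abs=0.05)
        fe = m.fe_params
        round_avg = np.mean([0.0] + [fe[f"C(round)[T.{r}]"] for r in range(1, 4)])
        sm_means = [
            fe["Intercept"] + round_avg + (fe.get(f"C(genotype)[T.{g}]", 0.0))
            for g in range(20)
        ]
        est = mine.means.sort_values("genotype")["blue"].to_numpy()
        assert np.abs(est - np.asarray(sm_means)).max() < 0.02

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="round"):
            fit_genotype_means(pd.DataFrame({"genotype": [1], "value": [1.0]}))


class TestNullCalibration:
    def test_auto_routing_type_i_error(self):
        """Null paired normal data: the auto-routed test rejects at the
        nominal 5% level within 0.7 points over 10^4 replicates."""
        rng = np.random.default_rng(17)
        n_rep, n = 10_000, 20
        d = rng.normal(0.0, 1.0, (n_rep, n))
        rejections = 0
        for i in range(n_rep):
            rejections += paired_test(d[i])["p"] < 0.05
        rate = rejections / n_rep
        assert rate == pytest.approx(0.05, abs=0.007)
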