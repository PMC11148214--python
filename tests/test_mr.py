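"""MR engine: selection, clumping, harmonization and the estimator suite,
checked against independent normal-equations oracles and small simulations."""

import numpy as np
import pandas as pd
import pytest

from gdmliver import GwasSimConfig, simulate_gwas_pair
from gdmliver.mr import (
    HarmonizedSet,
    clump,
    cochran_q,
    f_statistics,
    harmonize,
    ivw,
    mr_egger,
    mr_presso,
    mvmr,
    select_instruments,
    wald_ratio,
    weighted_median,
)


def snp_row(rsid, pval=1e-9, eaf=0.3, ea="A", oa="G", beta=0.1, se=0.01,
            chrom=1, pos=1_000_000, n=100_000):
    return dict(rsid=rsid, chr=chrom, pos=pos, effect_allele=ea, other_allele=oa,
                eaf=eaf, beta=beta, se=se, pval=pval, n=n)


def make_h(beta_exp, se_exp, beta_out, se_out):
    m = len(beta_exp)
    table = pd.DataFrame({
        "rsid": [f"rs{i}" for i in range(m)],
        "beta_exp": beta_exp, "se_exp": se_exp,
        "beta_out": beta_out, "se_out": se_out,
        "eaf_exp": 0.3, "eaf_out": 0.3,
    })
    return HarmonizedSet(table, pd.DataFrame(columns=["rsid", "action"]))


# the fixed 3-SNP instance used for the WLS oracle comparisons
H3 = make_h([0.10, 0.20, 0.15], [0.01, 0.01, 0.01], [0.05, 0.08, 0.09], [0.02, 0.02, 0.02])


class TestSelection:
    def test_strict_boundaries(self):
        df = pd.DataFrame([
            snp_row("rs_at_p", pval=5.0e-8),
            snp_row("rs_pass", pval=4.9e-8),
            snp_row("rs_rare", pval=1e-9, eaf=0.995),
            snp_row("rs_maf_edge", pval=1e-9, eaf=0.01),
            snp_row("rs_excl", pval=1e-9),
        ])
        kept = select_instruments(df, exclusion_list=["rs_excl"])
        assert set(kept["rsid"]) == {"rs_pass"}

    def test_identity_and_empty(self):
        df = pd.DataFrame([snp_row("rs1"), snp_row("rs2")])
        assert len(select_instruments(df, exclusion_list=[])) == 2
        with pytest.raises(ValueError, match="no valid instruments"):
            select_instruments(df, p_threshold=1e-300)


class TestClump:
    def test_within_window_correlated_pruned(self):
        df = pd.DataFrame([
            snp_row("rsA", pval=1e-10, pos=1_000_000),
            snp_row("rsB", pval=1e-9, pos=1_000_000 + 5_000_000),  # 5,000 kb apart
        ])
        ld = pd.DataFrame([("rsA", "rsB", 0.5)], columns=["rsid_a", "rsid_b", "r2"])
        out = clump(df, ld)
        assert list(out["rsid"]) == ["rsA"]

    def test_r2_threshold_strict(self):
        df = pd.DataFrame([snp_row("rsA", pos=1_000_000), snp_row("rsB", pval=1e-8, pos=2_000_000)])
        ld = pd.DataFrame([("rsA", "rsB", 0.0005)], columns=["rsid_a", "rsid_b", "r2"])
        assert len(clump(df, ld)) == 2

    def test_outside_window_kept(self):
        df = pd.DataFrame([
            snp_row("rsA", pos=1_000_000),
            snp_row("rsB", pval=1e-8, pos=1_000_000 + 10_001_000),  # 10,001 kb apart
        ])
        ld = pd.DataFrame([("rsA", "rsB", 0.9)], columns=["rsid_a", "rsid_b", "r2"])
        assert len(clump(df, ld)) == 2

    def test_missing_positions_error(self):
        df = pd.DataFrame([snp_row("rsA")]).drop(columns=["pos"])
        with pytest.raises(ValueError, match="position"):
            clump(df, None)

    def test_greedy_optimality_vs_bruteforce(self):
        """On small random instances the output must equal an independently
        coded greedy reference, and no retained pair may violate the
        (window, r2) constraints."""
        rng = np.random.default_rng(42)
        for trial in range(20):
            m = int(rng.integers(5, 21))
            df = pd.DataFrame([
                snp_row(f"rs{i}", pval=float(rng.uniform(1e-12, 1e-8)),
                        chrom=int(rng.integers(1, 3)),
                        pos=int(rng.integers(1, 30_000) * 1000))
                for i in range(m)
            ])
            pairs = []
            for i in range(m):
                for j in range(i + 1, m):
                    if rng.random() < 0.4:
                        pairs.append((f"rs{i}", f"rs{j}", float(rng.uniform(0, 1))))
            ld = pd.DataFrame(pairs, columns=["rsid_a", "rsid_b", "r2"])
            out = clump(df, ld, r2_threshold=0.001, window_kb=10_000)

            # reference: plain greedy over explicitly sorted rows
            r2map = {}
            for a, b, r in pairs:
                r2map[(a, b)] = r2map[(b, a)] = r
            rows = sorted(df.to_dict("records"), key=lambda r: (r["pval"], r["rsid"]))
            kept, removed = [], set()
            for r in rows:
                if r["rsid"] in removed:
                    continue
                kept.append(r["rsid"])
                for s in rows:
                    if s["rsid"] in removed or s["rsid"] == r["rsid"]:
                        continue
                    if (s["chr"] == r["chr"] and abs(s["pos"] - r["pos"]) <= 10_000_000
                            and r2map.get((r["rsid"], s["rsid"]), 0.0) > 0.001):
                        removed.add(s["rsid"])
            assert sorted(out["rsid"]) == sorted(k for k in kept)
            # constraint check on the retained set
            sub = out.set_index("rsid")
            for a in sub.index:
                for b in sub.index:
                    if a < b and sub.loc[a, "chr"] == sub.loc[b, "chr"] \
                            and abs(sub.loc[a, "pos"] - sub.loc[b, "pos"]) <= 10_000_000:
                        assert r2map.get((a, b), 0.0) <= 0.001


class TestHarmonize:
    def test_flip_palindromic_mismatch(self):
        exposure = pd.DataFrame([
            snp_row("rs_flip", ea="A", oa="G", beta=0.10),
            snp_row("rs_pal", ea="A", oa="T", beta=0.10),
            snp_row("rs_mis", ea="A", oa="G", beta=0.10),
            snp_row("rs_only_exp", ea="A", oa="G"),
        ])
        outcome = pd.DataFrame([
            snp_row("rs_flip", ea="G", oa="A", beta=-0.05, eaf=0.7),
            snp_row("rs_pal", ea="A", oa="T", beta=0.02),
            snp_row("rs_mis", ea="A", oa="C", beta=0.02),
        ])
        h = harmonize(exposure, outcome)
        acts = dict(zip(h.actions["rsid"], h.actions["action"]))
        assert acts == {
            "rs_flip": "flipped", "rs_pal": "dropped_palindromic",
            "rs_mis": "dropped_mismatch", "rs_only_exp": "dropped_missing",
        }
        row = h.table.set_index("rsid").loc["rs_flip"]
        assert row["beta_out"] == pytest.approx(0.05)
        assert row["eaf_out"] == pytest.approx(0.3)

    def test_empty_intersection(self):
        with pytest.raises(ValueError):
            harmonize(pd.DataFrame([snp_row("rs1")]), pd.DataFrame([snp_row("rs2")]))


class TestDiagnostics:
    def test_f_values(self):
        h = make_h([0.1, 0.0316227766], [0.01, 0.01], [0.0, 0.0], [0.02, 0.02])
        with pytest.warns(UserWarning, match="weak"):
            f, mean_f = f_statistics(make_h([0.0316227766], [0.01], [0.0], [0.02]))
        assert mean_f == pytest.approx(10.0, rel=1e-8)
        f, mean_f = f_statistics(h)
        assert f.iloc[0] == pytest.approx(100.0)
        assert mean_f == pytest.approx((100 + 10) / 2, rel=1e-8)

    def test_cochran_q_homogeneous_and_df(self):
        h = make_h([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.10, 0.20], [0.02] * 3)
        q, dof, p = cochran_q(h)
        assert q == pytest.approx(0.0, abs=1e-20) and p == pytest.approx(1.0)
        h2 = make_h([0.1, 0.2, 0.4, 0.4], [0.01] * 4, [0.05, 0.10, 0.20, 0.20], [0.02] * 4)
        assert cochran_q(h2)[1] == dof + 1


class TestWaldAndIvw:
    def test_wald_examples(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert (est.beta, est.se) == (pytest.approx(0.5), pytest.approx(0.2))
        assert wald_ratio(0.1, 0.01, 0.0, 0.02).beta == 0.0
        flipped = wald_ratio(-0.1, 0.01, -0.05, 0.02)
        assert flipped.beta == pytest.approx(0.5) and flipped.se == pytest.approx(0.2)
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)

    def test_homogeneous_ratios(self):
        h = make_h([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.10, 0.20], [0.02] * 3)
        est = ivw(h)
        assert est.beta == pytest.approx(0.5)
        assert est.diagnostics["q_stat"] == pytest.approx(0.0, abs=1e-18)
        assert est.se == pytest.approx(est.diagnostics["se_fixed"])

    def test_single_snp_reduces_to_wald(self):
        h = make_h([0.1], [0.01], [0.05], [0.02])
        est = ivw(h)
        ref = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.beta == ref.beta and est.se == ref.se

    def test_wls_oracle_3snp(self):
        """IVW equals the zero-intercept weighted normal-equations slope."""
        x, y, w = H3.beta_exp, H3.beta_out, 1.0 / H3.se_out**2
        oracle = float(np.sum(w * x * y) / np.sum(w * x * x))
        oracle_se = float(np.sum(w * x * x) ** -0.5)
        est = ivw(H3, random_effects=False)
        np.testing.assert_allclose(est.beta, oracle, rtol=1e-9)
        np.testing.assert_allclose(est.se, oracle_se, rtol=1e-9)


class TestEgger:
    def test_line_through_origin(self):
        h = make_h([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.10, 0.20], [0.02] * 3)
        slope, intercept = mr_egger(h)
        assert slope.beta == pytest.approx(0.5)
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)

    def test_wls_oracle_with_intercept(self):
        rng = np.random.default_rng(5)
        m = 10
        h = make_h(rng.uniform(0.05, 0.2, m), np.full(m, 0.01),
                   rng.normal(0.02, 0.03, m), rng.uniform(0.01, 0.03, m))
        slope, intercept = mr_egger(h)
        W = np.diag(1.0 / h.se_out**2)
        X = np.column_stack([np.ones(m), h.beta_exp])
        coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ h.beta_out)
        np.testing.assert_allclose(intercept.beta, coef[0], rtol=1e-9)
        np.testing.assert_allclose(slope.beta, coef[1], rtol=1e-9)

    def test_orientation_invariance(self):
        h = make_h([0.1, -0.2, 0.4, 0.15], [0.01] * 4, [0.05, 0.10, 0.20, 0.02], [0.02] * 4)
        s1, i1 = mr_egger(h)
        flipped = make_h([0.1, 0.2, 0.4, 0.15], [0.01] * 4, [0.05, -0.10, 0.20, 0.02], [0.02] * 4)
        s2, i2 = mr_egger(flipped)
        assert s1.beta == pytest.approx(s2.beta) and i1.beta == pytest.approx(i2.beta)

    def test_min_snps(self):
        with pytest.raises(ValueError):
            mr_egger(make_h([0.1, 0.2], [0.01] * 2, [0.0, 0.0], [0.02] * 2))


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        h = make_h([1.0, 1.0, 1.0], [0.01] * 3, [0.4, 0.5, 0.6], [1.0] * 3)
        est = weighted_median(h, n_boot=10, seed=0)
        assert est.beta == pytest.approx(0.5)

    def test_seeding_contract(self):
        a = weighted_median(H3, n_boot=25, seed=123)
        b = weighted_median(H3, n_boot=25, seed=123)
        assert a.beta == b.beta and a.se == b.se
        c = weighted_median(H3, n_boot=25, seed=124)
        assert c.se != a.se


class TestPresso:
    def test_spike_in_outlier_detected(self, gwas_pair):
        exposure, outcome, ld, truth = gwas_pair
        h = harmonize(exposure, outcome)
        tab = h.table.copy()
        k = 5
        tab.loc[k, "beta_out"] += 10 * tab.loc[k, "se_out"]
        spiked = HarmonizedSet(tab, h.actions)
        # outlier p is Bonferroni-floored at m/n_sim, so n_sim must exceed m/alpha
        res = mr_presso(spiked, n_sim=4000, seed=3)
        assert tab.loc[k, "rsid"] in res.outliers
        assert res.global_p < 0.05
        # removing the injected outlier restores the uncontaminated estimate
        clean = ivw(h).beta
        assert abs(res.corrected.beta - clean) < abs(ivw(spiked).beta - clean)

    def test_p_floor_warning(self):
        with pytest.warns(UserWarning, match="resolve"):
            mr_presso(H3.table.pipe(lambda t: make_h([0.1, 0.2, 0.15, 0.12], [0.01] * 4,
                                                     [0.05, 0.08, 0.09, 0.07], [0.02] * 4)),
                      n_sim=100, seed=1, significance_threshold=1e-6)


class TestMvmr:
    def test_zero_second_exposure_reduces_to_ivw(self):
        X = np.column_stack([H3.beta_exp, np.zeros(3)])
        ests = mvmr(X, H3.beta_out, H3.se_out, exposures=["alt", "bmi"])
        ref = ivw(H3)
        assert ests[0].beta == pytest.approx(ref.beta, rel=1e-9)
        assert ests[0].se == pytest.approx(ref.se, rel=1e-9)
        assert np.isnan(ests[1].beta)

    def test_single_exposure_equals_ivw(self):
        ests = mvmr(H3.beta_exp[:, None], H3.beta_out, H3.se_out)
        ref = ivw(H3)
        np.testing.assert_allclose(ests[0].beta, ref.beta, rtol=1e-9)
        np.testing.assert_allclose(ests[0].se, ref.se, rtol=1e-9)

    def test_wls_oracle_two_exposures(self):
        rng = np.random.default_rng(8)
        m = 12
        X = rng.uniform(0.02, 0.2, size=(m, 2))
        y = X @ np.array([0.25, 0.1]) + rng.normal(0, 0.01, m)
        sy = rng.uniform(0.01, 0.02, m)
        W = np.diag(1.0 / sy**2)
        oracle = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        ests = mvmr(X, y, sy)
        np.testing.assert_allclose([e.beta for e in ests], oracle, rtol=1e-9)

    def test_duplicated_exposure_rank_error(self):
        X = np.column_stack([H3.beta_exp, H3.beta_exp])
        with pytest.raises(ValueError, match="rank"):
            mvmr(X, H3.beta_out, H3.se_out)

    def test_attenuation_under_mediation(self):
        """When part of the exposure effect flows through a second trait,
        the multivariable direct effect is smaller than the univariable
        total effect."""
        rng = np.random.default_rng(9)
        m = 100
        gx = rng.uniform(0.03, 0.1, m)
        # the exposure raises the mediator, which also affects the outcome
        gmed = 0.8 * gx + rng.normal(0, 0.01, m)
        sy = np.full(m, 0.01)
        theta_direct, theta_med = 0.15, 0.2
        y = theta_direct * gx + theta_med * gmed + rng.normal(0, sy)
        total = ivw(make_h(gx, np.full(m, 0.005), y, sy))
        direct = mvmr(np.column_stack([gx, gmed]), y, sy)[0]
        assert direct.beta < total.beta


def test_full_orientation_invariance(gwas_pair):
    """Flipping a SNP's alleles in both studies (with eaf complement) leaves
    every harmonized estimate unchanged."""
    exposure, outcome, ld, _ = gwas_pair
    exp2, out2 = exposure.copy(), outcome.copy()
    for df in (exp2, out2):
        df.loc[0, ["effect_allele", "other_allele"]] = df.loc[0, ["other_allele", "effect_allele"]].to_numpy()
        df.loc[0, "beta"] = -df.loc[0, "beta"]
        df.loc[0, "eaf"] = 1.0 - df.loc[0, "eaf"]
    h1, h2 = harmonize(exposure, outcome), harmonize(exp2, out2)
    assert ivw(h1).beta == pytest.approx(ivw(h2).beta, rel=1e-12)
    assert mr_egger(h1)[0].beta == pytest.approx(mr_egger(h2)[0].beta, rel=1e-12)
    assert weighted_median(h1, n_boot=2, seed=0).beta == pytest.approx(
        weighted_median(h2, n_boot=2, seed=0).beta, rel=1e-12)
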