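import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ildsc.genio import standardize
from ildsc.scores import WindowSpec, additive_ld_scores, compute_scores
from ildsc.simulate import (
    PairList,
    TraitConfig,
    additive_variance_bound,
    assign_interactions,
    gwas,
    simulate_genotypes,
    simulate_trait,
    sparse_architecture_effects,
)


class TestSimulateGenotypes:
    def test_deterministic(self):
        a = simulate_genotypes(50, 30, 0.8, seed=3)
        b = simulate_genotypes(50, 30, 0.8, seed=3)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)

    def test_marginal_frequencies(self):
        n = 10_000
        panel = simulate_genotypes(n, 25, 0.5, maf_low=0.1, maf_high=0.4, seed=9)
        rng = np.random.default_rng(9)
        target = rng.uniform(0.1, 0.4, size=25)  # same draw order as the generator
        freq = panel.genotypes.mean(axis=0) / 2.0
        # binomial 99% bounds on 2n draws
        half = sps.norm.ppf(0.995) * np.sqrt(target * (1 - target) / (2 * n))
        assert (np.abs(freq - target) < half + 1e-9).mean() > 0.85
        np.testing.assert_allclose(freq, target, atol=0.03)

    def test_zero_decay_independent(self):
        panel = simulate_genotypes(500, 1001, 0.0, seed=1)
        std = standardize(panel, min_maf=0.0)
        rs = np.array([
            np.mean(std.matrix[:, k] * std.matrix[:, k + 1]) for k in range(1000)
        ])
        assert abs(rs.mean()) < 3 * rs.std() / np.sqrt(len(rs))

    def test_positive_decay_creates_ld(self):
        panel = simulate_genotypes(800, 200, 0.95, seed=2)
        std = standardize(panel, min_maf=0.0)
        rs = np.array([
            np.mean(std.matrix[:, k] * std.matrix[:, k + 1]) for k in range(std.J - 1)
        ])
        assert rs.mean() > 0.3

    def test_block_structure(self):
        panel = simulate_genotypes(600, 100, ld_blocks=(0.0, 0.95, 10), seed=4)
        std = standardize(panel, min_maf=0.0)
        rs = np.array([
            np.mean(std.matrix[:, k] * std.matrix[:, k + 1]) for k in range(std.J - 1)
        ])
        # decay alternates every 10 variants; tight blocks show much higher r
        assert rs[::2].mean() != pytest.approx(rs[1::2].mean(), abs=1e-6)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            simulate_genotypes(10, 5, 1.0)
        with pytest.raises(ValueError):
            simulate_genotypes(10, 5, 0.5, maf_low=0.4, maf_high=0.3)


class TestAssignInteractions:
    def test_single_hub_partner_count(self):
        panel = simulate_genotypes(20, 100, 0.0, seed=5)  # bp = 1k..100k
        pl = assign_interactions(panel, group1_frac=0.01, group2_window_kb=10, seed=5)
        assert len(pl.group1) == 1
        hub = pl.group1[0]
        lo, hi = max(hub - 10, 0), min(hub + 10, 99)
        assert pl.M == (hi - lo)

    def test_interior_hub_has_20_partners(self):
        panel = simulate_genotypes(20, 100, 0.0, seed=6)
        for seed in range(20):
            pl = assign_interactions(panel, 0.01, 10, seed=seed)
            hub = pl.group1[0]
            if 10 <= hub <= 89:
                assert pl.M == 20
                return
        pytest.skip("no interior hub drawn")

    def test_all_pairs(self):
        panel = simulate_genotypes(20, 12, 0.0, seed=7)
        pl = assign_interactions(panel, 1.0, 1000, seed=7)
        assert pl.M == 12 * 11 // 2

    def test_matches_bruteforce_set(self):
        panel = simulate_genotypes(20, 60, 0.0, seed=8)
        pl = assign_interactions(panel, 0.1, 7, seed=8)
        bp = panel.variants["bp"].to_numpy()
        expected = set()
        for hub in pl.group1:
            for k in range(60):
                if k != hub and abs(bp[k] - bp[hub]) <= 7000:
                    expected.add((min(hub, k), max(hub, k)))
        assert set(pl.pairs) == expected
        assert len(pl.pairs) == len(set(pl.pairs))

    def test_too_few_hubs(self):
        panel = simulate_genotypes(20, 30, 0.0, seed=9)
        with pytest.raises(ValueError):
            assign_interactions(panel, 0.001, 10, seed=9)


class TestSimulateTrait:
    def test_pure_additive(self):
        panel = simulate_genotypes(400, 100, 0.5, seed=10)
        tr = simulate_trait(panel, None, TraitConfig(h2=0.6, rho=1.0, seed=1))
        assert tr.theta == {}
        assert tr.realized_var["int"] == 0.0

    def test_exact_variance_decomposition(self):
        panel = simulate_genotypes(500, 120, 0.7, seed=11)
        pairs = assign_interactions(panel, 0.1, 10, seed=11)
        cfg = TraitConfig(h2=0.6, rho=0.5, seed=2)
        tr = simulate_trait(panel, pairs, cfg)
        assert np.var(tr.y) == pytest.approx(1.0, abs=1e-10)
        assert sum(tr.realized_var.values()) == pytest.approx(1.0, abs=1e-10)
        assert tr.realized_var["add"] == pytest.approx(0.3, abs=1e-12)
        assert tr.realized_var["int"] == pytest.approx(0.3, abs=1e-12)
        assert tr.realized_var["noise"] == pytest.approx(0.4, abs=1e-12)

    def test_same_seed_identical(self):
        panel = simulate_genotypes(200, 60, 0.5, seed=12)
        pairs = assign_interactions(panel, 0.1, 10, seed=12)
        cfg = TraitConfig(h2=0.3, rho=0.8, seed=5)
        a = simulate_trait(panel, pairs, cfg)
        b = simulate_trait(panel, pairs, cfg)
        np.testing.assert_array_equal(a.y, b.y)

    def test_rho_lt_1_requires_pairs(self):
        panel = simulate_genotypes(100, 30, 0.5, seed=13)
        with pytest.raises(ValueError, match="pair"):
            simulate_trait(panel, None, TraitConfig(h2=0.6, rho=0.5, seed=1))

    def test_infeasible_budget(self):
        with pytest.raises(ValueError, match="exceed"):
            TraitConfig(h2=0.3, var_extra=0.5, extra="gxe")

    def test_gxe_component(self):
        panel = simulate_genotypes(300, 80, 0.5, seed=14)
        pairs = assign_interactions(panel, 0.1, 10, seed=14)
        cfg = TraitConfig(h2=0.6, rho=2 / 3, var_extra=0.15, extra="gxe",
                          gxe_w=1.5, seed=3)
        tr = simulate_trait(panel, pairs, cfg)
        assert tr.realized_var["extra"] == pytest.approx(0.15, abs=1e-12)
        assert tr.realized_var["add"] == pytest.approx(0.3, abs=1e-12)
        assert tr.realized_var["int"] == pytest.approx(0.15, abs=1e-12)
        assert np.var(tr.y) == pytest.approx(1.0, abs=1e-10)

    def test_gxancestry_component(self):
        panel = simulate_genotypes(300, 80, 0.5, seed=15)
        cfg = TraitConfig(h2=0.6, rho=1.0, var_extra=0.2, extra="gxancestry",
                          k_pcs=5, seed=4)
        tr = simulate_trait(panel, None, cfg)
        assert tr.realized_var["extra"] == pytest.approx(0.2, abs=1e-12)
        assert len(tr.gamma) == 5

    def test_dominance_component(self):
        panel = simulate_genotypes(300, 80, 0.5, seed=16)
        cfg = TraitConfig(h2=0.6, rho=1.0, include_dominance=True, var_dom=0.1, seed=5)
        tr = simulate_trait(panel, None, cfg)
        assert tr.realized_var["dom"] == pytest.approx(0.1, abs=1e-12)
        assert tr.realized_var["add"] == pytest.approx(0.5, abs=1e-12)

    def test_orthogonal_components(self):
        # components are orthogonalised in-sample, so the decomposition
        # identity var(y) = sum of realized parts holds exactly
        panel = simulate_genotypes(400, 100, 0.6, seed=17)
        pairs = assign_interactions(panel, 0.1, 10, seed=17)
        cfg = TraitConfig(h2=0.6, rho=0.5, include_dominance=True, var_dom=0.1, seed=6)
        tr = simulate_trait(panel, pairs, cfg)
        assert np.var(tr.y) == pytest.approx(sum(tr.realized_var.values()), abs=1e-9)

    def test_effect_corr_runs(self):
        panel = simulate_genotypes(300, 80, 0.5, seed=18)
        pairs = assign_interactions(panel, 0.1, 10, seed=18)
        cfg = TraitConfig(h2=0.6, rho=0.5, effect_corr=0.8, seed=7)
        tr = simulate_trait(panel, pairs, cfg)
        assert np.var(tr.y) == pytest.approx(1.0, abs=1e-10)
        assert len(tr.theta) == pairs.M


class TestSparseArchitecture:
    def test_percentile_100_all_causal(self):
        panel = simulate_genotypes(200, 50, 0.5, seed=19)
        std = standardize(panel, min_maf=0.0)
        ell = additive_ld_scores(std, WindowSpec("snps", 10))["L2"].to_numpy()
        beta = sparse_architecture_effects(panel, ell, 100, "top", seed=19)
        assert (beta != 0).all()

    def test_counting(self):
        panel = simulate_genotypes(100, 1000, 0.5, seed=20)
        std = standardize(panel, min_maf=0.0)
        ell = np.arange(std.J, dtype=float)
        beta = sparse_architecture_effects(panel, ell, 10, "top", seed=20)
        assert (beta != 0).sum() == std.J // 10

    def test_selection_matches_sort(self):
        panel = simulate_genotypes(150, 200, 0.5, seed=21)
        std = standardize(panel, min_maf=0.0)
        rng = np.random.default_rng(21)
        ell = rng.uniform(1, 9, std.J)
        for side in ("top", "bottom"):
            beta = sparse_architecture_effects(panel, ell, 25, side, seed=21)
            chosen = set(np.flatnonzero(beta != 0))
            k = len(chosen)
            order = np.argsort(ell, kind="stable")
            expected = set(order[-k:]) if side == "top" else set(order[:k])
            assert chosen == expected

    def test_target_variance(self):
        panel = simulate_genotypes(200, 100, 0.5, seed=22)
        std = standardize(panel, min_maf=0.0)
        ell = np.ones(std.J)
        beta = sparse_architecture_effects(panel, ell, 50, "top", h2=0.4, seed=22)
        g = std.matrix @ beta
        assert np.mean((g - g.mean()) ** 2) == pytest.approx(0.4, abs=1e-10)

    def test_bad_args(self):
        panel = simulate_genotypes(50, 20, 0.5, seed=23)
        std = standardize(panel, min_maf=0.0)
        with pytest.raises(ValueError):
            sparse_architecture_effects(panel, np.ones(std.J), 10, "middle")
        with pytest.raises(ValueError):
            sparse_architecture_effects(panel, np.ones(std.J + 3), 10, "top")


class TestGwas:
    def test_exact_fit(self):
        panel = simulate_genotypes(500, 10, 0.0, seed=24)
        std = standardize(panel, min_maf=0.0)
        y = std.matrix[:, 0]
        ss = gwas(panel, y)
        row = ss.table.set_index("snp").loc[std.variants["id"].iloc[0]]
        assert row["chisq"] == pytest.approx(std.N, rel=1e-10)

    def test_orthogonal_variant(self):
        panel = simulate_genotypes(400, 5, 0.0, seed=25)
        std = standardize(panel, min_maf=0.0)
        x0 = std.matrix[:, 0]
        y = np.random.default_rng(0).standard_normal(std.N)
        y = y - x0 * (x0 @ y) / (x0 @ x0)
        ss = gwas(panel, y)
        assert ss.table["chisq"].iloc[0] == pytest.approx(0.0, abs=1e-18)

    def test_covariate_projection_oracle(self):
        rng = np.random.default_rng(26)
        panel = simulate_genotypes(300, 8, 0.3, seed=26)
        std = standardize(panel, min_maf=0.0)
        cov = rng.standard_normal((300, 2))
        y = rng.standard_normal(300)
        ss = gwas(panel, y, covariates=cov)
        c = np.column_stack([np.ones(300), cov])
        proj = np.eye(300) - c @ np.linalg.solve(c.T @ c, c.T)
        yr = proj @ y
        for j in range(std.J):
            xr = proj @ std.matrix[:, j]
            bj = (xr @ yr) / (xr @ xr)
            assert ss.table["chisq"].iloc[j] == pytest.approx(300 * bj**2, rel=1e-9)

    def test_rank_deficient_covariates(self):
        panel = simulate_genotypes(100, 5, 0.0, seed=27)
        cov = np.ones((100, 2))
        with pytest.raises(ValueError, match="rank"):
            gwas(panel, np.zeros(100), covariates=cov)

    def test_drop_variants(self):
        panel = simulate_genotypes(100, 10, 0.0, seed=28)
        ss = gwas(panel, np.random.default_rng(1).standard_normal(100),
                  drop_variants={0, 3})
        assert len(ss) <= 8


class TestAdditiveVarianceBound:
    def test_theta_zero_reduction(self, rng):
        maf = rng.uniform(0.05, 0.5, 10)
        beta = rng.standard_normal(10)
        sigma, eta = additive_variance_bound(maf, beta, {})
        np.testing.assert_allclose(eta, beta)
        assert sigma == pytest.approx(np.sum(2 * maf * (1 - maf) * beta**2))

    def test_two_locus_enumeration_oracle(self):
        p = np.array([0.3, 0.4])
        beta = np.array([0.1, 0.2])
        theta = {(0, 1): 0.5}
        sigma, eta = additive_variance_bound(p, beta, theta)
        # enumerate the 9 HWE genotype states under linkage equilibrium and
        # sum the per-locus regression variances
        probs = {}
        for x1 in (0, 1, 2):
            for x2 in (0, 1, 2):
                probs[(x1, x2)] = sps.binom.pmf(x1, 2, p[0]) * sps.binom.pmf(x2, 2, p[1])
        states = np.array(list(probs))
        w = np.array(list(probs.values()))
        g = beta[0] * states[:, 0] + beta[1] * states[:, 1] + 0.5 * states[:, 0] * states[:, 1]
        expected = 0.0
        etas = []
        for locus in (0, 1):
            x = states[:, locus]
            mx = np.sum(w * x)
            vx = np.sum(w * (x - mx) ** 2)
            cov = np.sum(w * (x - mx) * (g - np.sum(w * g)))
            etas.append(cov / vx)
            expected += cov**2 / vx
        assert sigma == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(eta, etas, atol=1e-12)

    def test_quadratic_scaling(self, rng):
        maf = rng.uniform(0.05, 0.5, 6)
        beta = rng.standard_normal(6)
        theta = {(0, 1): 0.3, (2, 5): -0.2}
        s1, _ = additive_variance_bound(maf, beta, theta)
        s2, _ = additive_variance_bound(maf, 2 * beta, {k: 2 * v for k, v in theta.items()})
        assert s2 == pytest.approx(4 * s1, rel=1e-12)

    def test_pair_out_of_range(self):
        with pytest.raises(IndexError):
            additive_variance_bound(np.array([0.2]), np.array([0.1]), {(0, 5): 1.0})

    def test_bad_maf(self):
        with pytest.raises(ValueError):
            additive_variance_bound(np.array([0.0]), np.array([0.1]), {})


class TestTagging:
    def test_gwas_beta_tracks_tagged_truth(self):
        # marginal estimates regressed on the realized per-SNP genetic signal
        # (R beta + V theta, computed in-sample) have slope ~ 1
        panel = simulate_genotypes(4000, 150, 0.7, seed=29)
        pairs = assign_interactions(panel, 0.1, 10, seed=29)
        cfg = TraitConfig(h2=0.6, rho=0.5, seed=8)
        tr = simulate_trait(panel, pairs, cfg)
        std = standardize(panel, min_maf=0.0)
        n = std.N
        genetic = tr.y - tr.eps - np.mean(tr.y - tr.eps)
        pred = std.matrix.T @ genetic / n  # per-SNP tagged expectation
        ss = gwas(panel, tr.y)
        bhat = np.sign(std.matrix.T @ (tr.y - tr.y.mean()) / n) * np.sqrt(
            ss.table["chisq"].to_numpy() / n
        )
        slope = np.polyfit(pred, bhat, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_unobserved_interactions_shrink_theta(self):
        # hiding interacting variants from the GWAS lowers the interaction
        # coefficient on average (never inflates it systematically)
        from ildsc.regress import fit_ildsc

        panel = simulate_genotypes(1500, 600, ld_blocks=(0.4, 0.97, 25),
                                   maf_low=0.02, seed=30)
        sc = compute_scores(panel, specs=[WindowSpec("snps", 50)],
                            ell_spec=WindowSpec("cm", 1.0), alpha=0.0)
        full_theta, drop_theta = [], []
        for rep in range(8):
            pairs = assign_interactions(panel, 0.1, 10, seed=100 + rep)
            cfg = TraitConfig(h2=0.6, rho=0.5, seed=200 + rep)
            tr = simulate_trait(panel, pairs, cfg)
            inter = sorted({k for p in pairs.pairs for k in p})
            rng = np.random.default_rng(rep)
            hide = set(rng.choice(inter, size=len(inter) // 2, replace=False).tolist())
            ss_full = gwas(panel, tr.y)
            ss_drop = gwas(panel, tr.y, drop_variants=hide)
            f1 = fit_ildsc(ss_full, sc, 50, n_blocks=50)
            f2 = fit_ildsc(ss_drop, sc, 50, n_blocks=50)
            full_theta.append(f1.pve_int)
            drop_theta.append(f2.pve_int)
        assert np.mean(drop_theta) < np.mean(full_theta)
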