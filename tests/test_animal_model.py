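import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

from oatol import animal_model as am
from oatol.pedigree import Pedigree, a_inverse
from oatol.simulate import (
    TRAITS,
    DesignSpec,
    default_truth,
    generate_breeding_design,
    simulate_trait_values,
)


@pytest.fixture(scope="module")
def fitted_chain(two_set_design):
    """A short chain on a 6-block design, shared across summary tests."""
    spec = DesignSpec(n_blocks=6, seed=19)
    ped, tanks = generate_breeding_design(spec)
    tt = simulate_trait_values(ped, tanks, default_truth(), seed=23)
    model = am.model_from_tables(tt, ped)
    prior = am.prior_from_data(tt)
    return am.run_gibbs(model, prior, n_iter=1500, burn_in=300, thin=5, seed=29)


class TestChainLength:
    def test_published_bookkeeping(self):
        assert am.chain_length(150_000, 1_000, 80) == 1862

    def test_sampler_honours_bookkeeping(self, fitted_chain):
        assert len(fitted_chain) == am.chain_length(1500, 300, 5)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            am.chain_length(100, 100, 5)
        with pytest.raises(ValueError):
            am.chain_length(100, 10, 0)


class TestPrior:
    def _table(self, var_scale=1.0):
        rng = np.random.default_rng(1)
        rows = []
        for trt in ("ambient", "acidified"):
            for k in range(20):
                rows.append(
                    {
                        "treatment": trt,
                        "mortality_rate": rng.normal(0.05, 0.02) * np.sqrt(var_scale),
                        "growth": rng.normal(1.5, 0.5) * np.sqrt(var_scale),
                    }
                )
        return pd.DataFrame(rows)

    def test_quarter_of_observed_variance_with_low_belief(self):
        tbl = self._table()
        prior = am.prior_from_data(tbl)
        for comp in am.COMPONENTS:
            assert prior.nu[comp] == 0.001
            v0 = prior.scale[comp] / prior.nu[comp]
            assert np.allclose(v0 - np.diag(np.diag(v0)), 0.0)  # diagonal
        amb = tbl[tbl.treatment == "ambient"]
        assert prior.scale["G"][0, 0] / 0.001 == pytest.approx(
            amb["mortality_rate"].var(ddof=1) / 4
        )

    def test_doubling_values_quadruples_scale(self):
        tbl = self._table()
        doubled = tbl.assign(
            mortality_rate=2 * tbl.mortality_rate, growth=2 * tbl.growth
        )
        p1 = am.prior_from_data(tbl)
        p2 = am.prior_from_data(doubled)
        assert np.allclose(p2.scale["G"], 4 * p1.scale["G"])

    def test_zero_variance_rejected(self):
        tbl = self._table()
        tbl["growth"] = 1.0
        with pytest.raises(ValueError):
            am.prior_from_data(tbl)


class TestInverseWishart:
    def test_moments_match_theory(self):
        """Mean of IW(df, S) is S / (df - p - 1)."""
        rng = np.random.default_rng(5)
        S = np.array([[2.0, 0.5], [0.5, 1.0]])
        df = 12.0
        draws = np.array([am._rinvwishart(rng, df, S) for _ in range(20_000)])
        expected = S / (df - 3)
        se = draws.std(axis=0) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 4 * se)

    def test_draws_positive_definite(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            d = am._rinvwishart(rng, 6.0, np.eye(4))
            assert np.linalg.eigvalsh(d).min() > 0

    def test_df_too_small_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError):
            am._rinvwishart(rng, 2.5, np.eye(4))


class TestConjugacy:
    def test_single_component_matches_closed_form(self):
        """With only the residual component, a fixed mean and complete
        data, the sampler must reproduce the analytic inverse-Wishart
        posterior IW(nu + n, nu*V0 + S)."""
        rng = np.random.default_rng(0)
        n = 150
        Rtrue = np.array(
            [[1.0, 0.3, 0.0, 0.0], [0.3, 1.5, 0.2, 0.0],
             [0.0, 0.2, 0.8, 0.1], [0.0, 0.0, 0.1, 1.2]]
        )
        y = rng.multivariate_normal(np.zeros(4), Rtrue, size=n)
        ped = Pedigree([f"i{k}" for k in range(n)], [None] * n, [None] * n)
        model = am.ModelSpec(
            traits=TRAITS,
            y=y,
            mask=np.ones((n, 4), bool),
            record_animal=np.arange(n),
            record_dam=np.zeros(n, dtype=int),
            record_block=np.zeros(n, dtype=int),
            dam_levels=["d0"],
            block_levels=["b0"],
            pedigree=ped,
            a_inv=sparse.identity(n, format="csr"),
        )
        nu, v0 = 0.001, np.eye(4) * 0.25
        prior = am.PriorSpec(
            scale={c: nu * v0 for c in am.COMPONENTS}, nu={c: nu for c in am.COMPONENTS}
        )
        chain = am.run_gibbs(
            model, prior, n_iter=3000, burn_in=200, thin=1, seed=3,
            components=("R",), fixed_mu=np.zeros(4),
        )
        analytic_mean = (nu * v0 + y.T @ y) / (nu + n - 5)
        mc_se = chain.R.std(axis=0) / np.sqrt(len(chain))
        assert np.all(np.abs(chain.R.mean(axis=0) - analytic_mean) < 3 * mc_se)


class TestChainStorage:
    def test_stored_components_symmetric_psd(self, fitted_chain):
        for comp in am.COMPONENTS:
            arr = fitted_chain.component(comp)
            assert np.allclose(arr, arr.transpose(0, 2, 1))
            eigs = np.linalg.eigvalsh(arr)
            assert eigs.min() > -1e-12

    def test_csv_round_trip(self, fitted_chain, tmp_path):
        path = tmp_path / "chain.csv"
        fitted_chain.write_csv(path)
        back = am.PosteriorChain.read_csv(path)
        assert np.allclose(back.G, fitted_chain.G)
        assert np.allclose(back.mu, fitted_chain.mu)

    def test_reproducible_bit_for_bit(self):
        ped, tanks = generate_breeding_design(DesignSpec(n_blocks=5, seed=43))
        tt = simulate_trait_values(ped, tanks, default_truth(), seed=31)
        model = am.model_from_tables(tt, ped)
        prior = am.prior_from_data(tt)
        c1 = am.run_gibbs(model, prior, 500, 100, 2, seed=5)
        c2 = am.run_gibbs(model, prior, 500, 100, 2, seed=5)
        assert np.array_equal(c1.G, c2.G)
        assert np.array_equal(c1.mu, c2.mu)


class TestDerivedQuantities:
    def test_heritability_of_equal_components_is_quarter(self, fitted_chain):
        eq = am.PosteriorChain(
            traits=TRAITS,
            mu=np.zeros((30, 4)),
            G=np.tile(np.eye(4), (30, 1, 1)),
            M=np.tile(np.eye(4), (30, 1, 1)),
            B=np.tile(np.eye(4), (30, 1, 1)),
            R=np.tile(np.eye(4), (30, 1, 1)),
        )
        s = am.heritability(eq, "mortality_ambient")
        assert s.mean == pytest.approx(0.25)
        assert s.lower == s.upper == pytest.approx(0.25)

    def test_heritability_one_when_only_genetic(self):
        z = np.zeros((25, 4, 4))
        only_g = am.PosteriorChain(
            traits=TRAITS, mu=np.zeros((25, 4)),
            G=np.tile(np.eye(4), (25, 1, 1)), M=z.copy(), B=z.copy(), R=z.copy(),
        )
        assert am.heritability(only_g, 0).mean == pytest.approx(1.0)

    def test_proportions_sum_to_one_in_every_sample(self, fitted_chain):
        total = fitted_chain.total
        shares = np.stack(
            [fitted_chain.component(c)[:, 0, 0] / total[:, 0, 0] for c in am.COMPONENTS]
        )
        assert np.allclose(shares.sum(axis=0), 1.0, atol=1e-12)

    def test_genetic_correlation_point_formula(self):
        """Published point G for mortality gives r_G = 0.496."""
        G4 = np.zeros((4, 4))
        G4[:2, :2] = [[2.48e-4, 2.10e-4], [2.10e-4, 7.23e-4]]
        G4[2, 2] = G4[3, 3] = 1.0
        chain = am.PosteriorChain(
            traits=TRAITS, mu=np.zeros((25, 4)),
            G=np.tile(G4, (25, 1, 1)),
            M=np.tile(np.eye(4), (25, 1, 1)),
            B=np.tile(np.eye(4), (25, 1, 1)),
            R=np.tile(np.eye(4), (25, 1, 1)),
        )
        r = am.genetic_correlation(chain, 0, 1)
        assert r.mean == pytest.approx(2.10e-4 / np.sqrt(2.48e-4 * 7.23e-4), rel=1e-9)
        assert r.mean == pytest.approx(0.496, abs=5e-4)

    def test_correlation_bounds_and_self(self, fitted_chain):
        r = am.genetic_correlation(fitted_chain, 0, 1)
        assert np.all(np.abs(r.samples) <= 1.0 + 1e-12)
        self_r = am.genetic_correlation(fitted_chain, 1, 1)
        assert self_r.mean == pytest.approx(1.0)
        m_self = am.maternal_correlation(fitted_chain, 2, 2)
        assert m_self.mean == pytest.approx(1.0)

    def test_diagonal_component_zero_correlation(self):
        diag = np.tile(np.diag([1.0, 2.0, 3.0, 4.0]), (25, 1, 1))
        chain = am.PosteriorChain(
            traits=TRAITS, mu=np.zeros((25, 4)),
            G=diag.copy(), M=diag.copy(), B=diag.copy(), R=diag.copy(),
        )
        assert am.genetic_correlation(chain, 0, 1).mean == 0.0
        assert am.maternal_correlation(chain, 0, 1).mean == 0.0

    def test_rescaling_invariance_of_ratios(self):
        """Per-trait rescaling of the data must leave heritabilities and
        correlations unchanged (same seed, scaled traits)."""
        ped, tanks = generate_breeding_design(DesignSpec(n_blocks=5, seed=47))
        tt = simulate_trait_values(ped, tanks, default_truth(), seed=37)
        scaled = tt.copy()
        scaled["mortality_rate"] = scaled["mortality_rate"] * 10
        scaled["growth"] = scaled["growth"] * 0.5
        chains = []
        for table in (tt, scaled):
            model = am.model_from_tables(table, ped)
            prior = am.prior_from_data(table)
            # short chain: the update rules are scale-equivariant, so the
            # two trajectories match draw for draw until floating-point
            # drift (amplified by the chaotic chain) desynchronizes them
            chains.append(am.run_gibbs(model, prior, 50, 5, 2, seed=41))
        h_a = am.heritability(chains[0], 0)
        h_b = am.heritability(chains[1], 0)
        assert np.allclose(h_a.samples, h_b.samples, rtol=1e-5)
        r_a = am.genetic_correlation(chains[0], 0, 1)
        r_b = am.genetic_correlation(chains[1], 0, 1)
        assert np.allclose(r_a.samples, r_b.samples, rtol=1e-5, atol=1e-5)


class TestConvergenceDiagnosticsReport:
    def test_report_covers_all_parameters(self, fitted_chain):
        diag = am.convergence_diagnostics(fitted_chain)
        # 4 means + 4 components x 10 unique entries
        assert len(diag) == 4 + 4 * 10
        assert diag["cvm_pvalue"].between(0, 1).all()

    def test_short_chain_rejected(self):
        tiny = am.PosteriorChain(
            traits=TRAITS, mu=np.zeros((50, 4)),
            G=np.tile(np.eye(4), (50, 1, 1)), M=np.tile(np.eye(4), (50, 1, 1)),
            B=np.tile(np.eye(4), (50, 1, 1)), R=np.tile(np.eye(4), (50, 1, 1)),
        )
        with pytest.raises(ValueError):
            am.convergence_diagnostics(tiny)
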