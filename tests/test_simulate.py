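import numpy as np
import pandas as pd
import pytest

from oatol.pedigree import additive_relationship_matrix
from oatol.simulate import (
    DesignSpec,
    TruthParams,
    default_truth,
    generate_breeding_design,
    simulate_daily_counts,
    simulate_lengths,
    simulate_study,
    simulate_trait_values,
    truth_from_proportions,
    write_study,
)


class TestDesignSpec:
    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            DesignSpec(n_blocks=0)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            DesignSpec(duplicate_family_fraction=1.5)


class TestTruthParams:
    def test_non_psd_rejected(self):
        bad = np.diag([1.0, 1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="positive semidefinite"):
            TruthParams(mu=np.zeros(4), G=bad, M=np.zeros((4, 4)), B=np.zeros((4, 4)), R=np.eye(4))

    def test_asymmetric_rejected(self):
        bad = np.eye(4)
        bad[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            TruthParams(mu=np.zeros(4), G=bad, M=np.zeros((4, 4)), B=np.zeros((4, 4)), R=np.eye(4))

    def test_default_truth_psd_and_json_round_trip(self, tmp_path):
        truth = default_truth()
        for mat in (truth.G, truth.M, truth.B, truth.R, truth.P):
            assert np.linalg.eigvalsh(mat).min() >= -1e-10
        truth.to_json(tmp_path / "t.json")
        back = TruthParams.from_json(tmp_path / "t.json")
        assert np.allclose(back.G, truth.G)

    def test_truth_from_proportions_matches_requested_shares(self):
        truth = truth_from_proportions(h2_mortality=0.2, maternal_proportion=0.3,
                                       block_proportion=0.4)
        P = truth.P
        assert truth.G[0, 0] / P[0, 0] == pytest.approx(0.2)
        assert truth.M[0, 0] / P[0, 0] == pytest.approx(0.3)
        assert truth.B[0, 0] / P[0, 0] == pytest.approx(0.4)
        assert truth.R[0, 0] / P[0, 0] == pytest.approx(0.1)
        r_g = truth.G[0, 1] / np.sqrt(truth.G[0, 0] * truth.G[1, 1])
        assert r_g == pytest.approx(0.45)


class TestGenerateBreedingDesign:
    def test_single_set_gives_nine_families(self):
        ped, tanks = generate_breeding_design(DesignSpec(n_blocks=1, sets_per_block=1, seed=2))
        families = {(t.sire_id, t.dam_id) for t in tanks}
        # capacity 12 >= 9 candidate families, so all are reared
        assert len(families) == 9
        assert int((ped.sire < 0).sum()) == 6

    def test_two_sets_give_eighteen_candidate_families(self, two_set_design):
        _, ped, tanks = two_set_design
        assert int((ped.sire < 0).sum()) == 12  # 2 sets x (3 sires + 3 dams)
        # 18 candidate families; capacity limits rearing to 12 slots
        reared = {t.family_id for t in tanks}
        assert len(reared) <= 12

    def test_no_duplicates_two_tanks_per_family(self):
        spec = DesignSpec(n_blocks=2, sets_per_block=1, duplicate_family_fraction=0.0, seed=3)
        _, tanks = generate_breeding_design(spec)
        per_family = pd.Series([t.family_id for t in tanks]).value_counts()
        assert (per_family == 2).all()  # one tank per treatment

    def test_both_treatments_per_reared_family(self, two_set_design):
        _, _, tanks = two_set_design
        df = pd.DataFrame([(t.family_id, t.treatment) for t in tanks], columns=["f", "trt"])
        per_family = df.groupby("f")["trt"].nunique()
        assert (per_family == 2).all()

    def test_capacity_respected(self):
        spec = DesignSpec(n_blocks=3, sets_per_block=2, duplicate_family_fraction=0.5, seed=9)
        _, tanks = generate_breeding_design(spec)
        df = pd.DataFrame([(t.block, t.treatment) for t in tanks], columns=["b", "trt"])
        assert df.value_counts().max() <= spec.max_tanks_per_treatment_per_block

    def test_deterministic_under_seed(self):
        spec = DesignSpec(n_blocks=2, seed=13)
        ped1, tanks1 = generate_breeding_design(spec)
        ped2, tanks2 = generate_breeding_design(spec)
        assert ped1.ids == ped2.ids
        assert [t.tank_id for t in tanks1] == [t.tank_id for t in tanks2]


class TestSimulateTraitValues:
    def test_zero_variance_returns_mu_exactly(self, two_set_design):
        _, ped, tanks = two_set_design
        mu = np.array([0.05, 0.07, 1.2, 1.3])
        z = np.zeros((4, 4))
        truth = TruthParams(mu=mu, G=z, M=z, B=z, R=z)
        tt = simulate_trait_values(ped, tanks, truth, seed=1)
        amb = tt[tt.treatment == "ambient"]
        acid = tt[tt.treatment == "acidified"]
        assert np.allclose(amb["mortality_rate"], mu[0])
        assert np.allclose(acid["mortality_rate"], mu[1])
        assert np.allclose(amb["growth"], mu[2])
        assert np.allclose(acid["growth"], mu[3])

    def test_non_psd_truth_rejected(self):
        bad = np.diag([1.0, 1.0, 1.0, -0.5])
        with pytest.raises(ValueError):
            TruthParams(mu=np.zeros(4), G=bad, M=bad, B=bad, R=bad)

    @pytest.mark.parametrize(
        "relationship,coefficient", [("full_sib", 0.5), ("half_sib", 0.25)]
    )
    def test_sib_covariance_matches_additive_expectation(self, relationship, coefficient):
        """Brute-force oracle: with M=B=R=0 the covariance of trait values
        between sib tank pairs is the relatedness coefficient times G."""
        from oatol.pedigree import Pedigree
        from oatol.simulate import TankRecord

        rng_seed = 17
        n_pairs = 2500
        g_diag = np.array([1.0, 2.0, 0.5, 1.5])
        z = np.zeros((4, 4))
        truth = TruthParams(mu=np.zeros(4), G=np.diag(g_diag), M=z, B=z, R=z)
        ids, sires, dams, tanks = [], [], [], []
        for k in range(n_pairs):
            s, d = f"s{k}", f"d{k}"
            ids += [s, d]
            sires += [None, None]
            dams += [None, None]
            if relationship == "full_sib":
                pair_parents = [(s, d), (s, d)]
            else:
                d2 = f"d{k}b"
                ids.append(d2)
                sires.append(None)
                dams.append(None)
                pair_parents = [(s, d), (s, d2)]
            for j, (ps, pd_) in enumerate(pair_parents):
                tid = f"t{k}_{j}"
                ids.append(tid)
                sires.append(ps)
                dams.append(pd_)
                # both tanks ambient so the pair shares the same trait
                tanks.append(TankRecord(tid, f"f{k}_{j}", ps, pd_, "blk01", "ambient"))
        ped = Pedigree(ids, sires, dams)
        tt = simulate_trait_values(ped, tanks, truth, seed=rng_seed)
        first = tt.iloc[0::2]["mortality_rate"].to_numpy()
        second = tt.iloc[1::2]["mortality_rate"].to_numpy()
        cov = np.cov(first, second)[0, 1]
        expected = coefficient * g_diag[0]
        se = np.sqrt((g_diag[0] ** 2 * (1 + coefficient**2)) / n_pairs)
        assert abs(cov - expected) < 3 * se

    def test_deterministic_under_seed(self, two_set_design):
        _, ped, tanks = two_set_design
        truth = default_truth()
        t1 = simulate_trait_values(ped, tanks, truth, seed=4)
        t2 = simulate_trait_values(ped, tanks, truth, seed=4)
        pd.testing.assert_frame_equal(t1, t2)


class TestSimulateDailyCounts:
    def test_zero_rate_keeps_all(self):
        counts = simulate_daily_counts(0.0, 50, 14, seed=1)
        assert np.array_equal(counts, np.full(15, 50))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_daily_counts(-0.1, 50, 14, seed=1)

    def test_series_non_increasing_and_bounded(self):
        counts = simulate_daily_counts(0.2, 50, 14, seed=2)
        assert counts[0] == 50
        assert (np.diff(counts) <= 0).all()
        assert counts.min() >= 0

    def test_binomial_thinning_expectation(self):
        """E[N_14] = 50 exp(-0.05*14) ~ 24.8 by iterated thinning."""
        rng = np.random.default_rng(5)
        finals = [simulate_daily_counts(0.05, 50, 14, rng)[-1] for _ in range(4000)]
        expected = 50 * np.exp(-0.7)
        se = np.std(finals, ddof=1) / np.sqrt(len(finals))
        assert abs(np.mean(finals) - expected) < 3 * se

    def test_huge_rate_kills_tank_immediately(self):
        counts = simulate_daily_counts(10.0, 50, 14, seed=3)
        assert counts[1] == 0


class TestSimulateLengths:
    def test_noiseless_difference_exact(self):
        d0, d14 = simulate_lengths(1.5, 6.0, 10, 0.0, seed=1)
        assert d14.mean() - d0.mean() == pytest.approx(1.5)

    def test_unbiased_over_replicates(self):
        rng = np.random.default_rng(8)
        diffs = [
            np.mean(b) - np.mean(a)
            for a, b in (simulate_lengths(1.5, 6.0, 10, 0.2, rng) for _ in range(4000))
        ]
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs) - 1.5) < 3 * se

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            simulate_lengths(1.0, 6.0, 0, 0.1, seed=1)


class TestSimulateStudy:
    def test_tables_written_and_consistent(self, small_study, tmp_path):
        paths = write_study(small_study, tmp_path)
        assert all(p.exists() for p in paths.values())
        counts = pd.read_csv(paths["counts"])
        tanks = pd.read_csv(paths["tanks"])
        assert set(counts["tank_id"]) == set(tanks["tank_id"])
        per_tank = counts.groupby("tank_id")["day"].count()
        assert (per_tank == 15).all()

    def test_study_deterministic_under_seed(self):
        s1 = simulate_study(DesignSpec(n_blocks=2, seed=21))
        s2 = simulate_study(DesignSpec(n_blocks=2, seed=21))
        pd.testing.assert_frame_equal(s1.counts, s2.counts)
        pd.testing.assert_frame_equal(s1.lengths, s2.lengths)
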