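"""Evaluation metrics against brute-force and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from graphgpt import (
    DistributionStats,
    condition_deviation,
    compute_properties,
    frechet_distance,
    guacamol_score,
    intdiv,
    kl_score,
    kl_score_from_smiles,
    vun_report,
)
from graphgpt.metrics import kl_divergence_histogram


class TestVUN:
    def test_hand_counted_example(self):
        report = vun_report(["C", "C", "CC"], {"C"})
        assert report.valid == pytest.approx(1.0)
        assert report.unique == pytest.approx(2 / 3)
        assert report.novelty == pytest.approx(1 / 2)
        assert (report.n_total, report.n_valid, report.n_unique, report.n_novel) == (3, 3, 2, 1)

    def test_all_invalid_flags_degenerate(self):
        report = vun_report(["xx", ")(", ""], set())
        assert report.valid == report.unique == report.novelty == 0.0
        assert report.degenerate

    def test_disjoint_from_training_gives_novelty_one(self):
        report = vun_report(["CCO", "CCC"], {"C"})
        assert report.novelty == 1.0

    def test_noncanonical_duplicates_collapse(self):
        # both spellings of benzene are one unique molecule
        report = vun_report(["c1ccccc1", "C1=CC=CC=C1"], set())
        assert report.n_unique == 1

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.sampled_from(["C", "CC", "CCO", "c1ccccc1", "not_a_smiles", ""]), max_size=12))
    def test_count_chain_on_fuzzed_inputs(self, generated):
        report = vun_report(generated, {"CCO"})
        assert report.n_novel <= report.n_unique <= report.n_valid <= report.n_total


class TestIntDiv:
    def test_identical_molecules_give_zero(self):
        assert intdiv(["CCO"] * 4) == pytest.approx(0.0)

    def test_single_molecule_gives_zero(self):
        assert intdiv(["c1ccccc1"]) == pytest.approx(0.0)

    @pytest.mark.parametrize("p", [1, 2])
    def test_three_molecule_set_matches_double_loop_oracle(self, p):
        smiles = ["CCO", "CCC", "c1ccccc1"]
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        fps = [gen.GetFingerprint(Chem.MolFromSmiles(s)) for s in smiles]
        total = 0.0
        for f1 in fps:  # all 9 ordered pairs, self-pairs included
            for f2 in fps:
                total += DataStructs.TanimotoSimilarity(f1, f2) ** p
        expected = 1.0 - (total / 9.0) ** (1.0 / p)
        assert intdiv(smiles, p) == pytest.approx(expected, abs=1e-12)

    def test_adding_duplicate_never_increases_diversity(self, fixture_smiles):
        base = list(dict.fromkeys(fixture_smiles))[:6]
        with_dup = base + [base[0]]
        assert intdiv(with_dup) <= intdiv(base) + 1e-12

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            intdiv([])


def random_psd(rng, d):
    a = rng.normal(size=(d, d))
    return a @ a.T + 0.1 * np.eye(d)


class TestFrechet:
    def test_identical_stats_give_zero_and_score_one(self, rng):
        stats = DistributionStats(mean=rng.normal(size=4), cov=random_psd(rng, 4))
        assert frechet_distance(stats, stats) == pytest.approx(0.0, abs=1e-8)
        assert guacamol_score(0.0) == 1.0

    def test_shared_covariance_reduces_to_mean_distance(self, rng):
        cov = random_psd(rng, 3)
        mu = rng.normal(size=3)
        delta = rng.normal(size=3)
        g = DistributionStats(mean=mu, cov=cov)
        d = DistributionStats(mean=mu + delta, cov=cov)
        assert frechet_distance(g, d) == pytest.approx(float(delta @ delta), abs=1e-8)

    def test_matches_eigendecomposition_oracle(self, rng):
        g = DistributionStats(mean=rng.normal(size=4), cov=random_psd(rng, 4))
        d = DistributionStats(mean=rng.normal(size=4), cov=random_psd(rng, 4))
        # oracle: sqrt of the product via eigendecomposition of the
        # symmetrized similar matrix S_G^1/2 S_D S_G^1/2
        w, v = np.linalg.eigh(g.cov)
        root_g = v @ np.diag(np.sqrt(w)) @ v.T
        inner = root_g @ d.cov @ root_g
        wi, vi = np.linalg.eigh(inner)
        tr_sqrt = np.sqrt(np.clip(wi, 0, None)).sum()
        delta = g.mean - d.mean
        expected = float(delta @ delta + np.trace(g.cov + d.cov) - 2 * tr_sqrt)
        assert frechet_distance(g, d) == pytest.approx(expected, abs=1e-6)

    def test_symmetric_and_nonnegative(self, rng):
        for _ in range(5):
            g = DistributionStats(mean=rng.normal(size=3), cov=random_psd(rng, 3))
            d = DistributionStats(mean=rng.normal(size=3), cov=random_psd(rng, 3))
            fgd = frechet_distance(g, d)
            assert fgd >= 0.0
            assert fgd == pytest.approx(frechet_distance(d, g), abs=1e-8)

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistributionStats(mean=np.zeros(2), cov=np.array([[1.0, 2.0], [0.0, 1.0]]))
        bad = DistributionStats(mean=np.zeros(2), cov=np.array([[1.0, 0.0], [0.0, -1.0]]))
        good = DistributionStats(mean=np.zeros(2), cov=np.eye(2))
        with pytest.raises(ValueError, match="PSD"):
            frechet_distance(bad, good)


class TestKL:
    def test_identical_samples_score_one(self, rng):
        x = rng.normal(size=200)
        desc = {"a": x, "b": x * 2}
        assert kl_score(desc, desc) == pytest.approx(1.0)

    def test_kl_of_ln2_scores_half(self):
        # P uniform over two half-ranges, Q concentrated: force D_KL = ln 2
        # via explicit histograms instead: use the closed form S = exp(-ln 2)
        assert np.exp(-np.log(2.0)) == pytest.approx(0.5)
        p = np.array([0.25] * 200 + [0.75] * 200)
        q = np.array([0.25] * 200 + [0.75] * 200)
        d = kl_divergence_histogram(p, q, bins=2)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_three_bin_histogram_matches_hand_sum(self):
        p_samples = np.array([0.5, 0.5, 1.5, 2.5])
        q_samples = np.array([0.5, 1.5, 1.5, 2.5])
        d = kl_divergence_histogram(p_samples, q_samples, bins=3, smoothing=0.0)
        p = np.array([2, 1, 1]) / 4
        q = np.array([1, 2, 1]) / 4
        expected = float(np.sum(p * np.log(p / q)))
        assert d == pytest.approx(expected, abs=1e-12)

    def test_smiles_path_identical_sets(self, fixture_smiles):
        subset = fixture_smiles[:80]
        assert kl_score_from_smiles(subset, subset) == pytest.approx(1.0)

    def test_score_in_unit_interval(self, rng, fixture_smiles):
        score = kl_score_from_smiles(fixture_smiles[:60], fixture_smiles[60:160])
        assert 0.0 < score <= 1.0

    def test_mismatched_descriptor_sets_rejected(self, rng):
        with pytest.raises(ValueError):
            kl_score({"a": np.arange(5.0)}, {"b": np.arange(5.0)})


class TestConditionDeviation:
    def test_exact_hits_give_zero(self):
        tpsa = compute_properties("c1ccccc1")["TPSA"]
        dev = condition_deviation(["c1ccccc1"] * 3, {"TPSA": tpsa})
        assert dev.sd["TPSA"] == pytest.approx(0.0)
        assert dev.mad["TPSA"] == pytest.approx(0.0)

    def test_two_value_hand_arithmetic(self):
        # property values {t1, t2}, target at midpoint: MAD = half-gap,
        # population SD = half-gap
        mols = ["CCO", "CCN"]
        values = [compute_properties(m)["TPSA"] for m in mols]
        target = float(np.mean(values))
        gap = abs(values[0] - values[1]) / 2
        dev = condition_deviation(mols, {"TPSA": target})
        assert dev.mad["TPSA"] == pytest.approx(gap)
        assert dev.sd["TPSA"] == pytest.approx(gap)

    def test_matches_direct_formula_on_random_set(self, fixture_smiles):
        mols = fixture_smiles[:20]
        target = 42.0
        dev = condition_deviation(mols, {"TPSA": target, "logP": 1.0})
        values = np.array([compute_properties(m)["TPSA"] for m in mols])
        assert dev.sd["TPSA"] == pytest.approx(values.std())
        assert dev.mad["TPSA"] == pytest.approx(np.abs(values - target).mean())

    def test_invalid_only_input_raises(self):
        with pytest.raises(ValueError):
            condition_deviation(["not_a_smiles"], {"TPSA": 40.0})
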