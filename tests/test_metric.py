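"""Correlation measures, partition sampler, simulation, and score curve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snipscan import (
    MISSING,
    UNDEFINED,
    HaplotypeDiseaseModel,
    MetricConstructionConfig,
    MetricCurve,
    genotype_r2,
    haplotype_r2_from_counts,
    run_metric_construction,
    sample_haplotype_partition,
    score,
    simulate_case_control,
    table1_fixture,
)
from snipscan.metric import MODEL_PENETRANCES


# ---------------------------------------------------------------------------
# genotype_r2
# ---------------------------------------------------------------------------

class TestGenotypeR2:
    def test_self_correlation_is_one(self):
        g = np.array([0, 1, 2, 0, 1], dtype=np.int8)
        assert genotype_r2(g, g) == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        g = np.array([0, 1, 2], dtype=np.int8)
        assert genotype_r2(g, np.ones(3, dtype=np.int8)) is UNDEFINED

    def test_hand_computed_six_pairs(self):
        g1 = np.array([0, 0, 1, 1, 2, 2], dtype=np.int8)
        g2 = np.array([0, 1, 0, 1, 2, 2], dtype=np.int8)
        expected = np.corrcoef(g1, g2)[0, 1] ** 2
        assert genotype_r2(g1, g2) == pytest.approx(expected)

    def test_pairwise_complete_drops_missing(self):
        g1 = np.array([0, 0, 1, 1, 2, 2, MISSING], dtype=np.int8)
        g2 = np.array([0, 1, 0, 1, 2, MISSING, 2], dtype=np.int8)
        expected = np.corrcoef(g1[:5], g2[:5])[0, 1] ** 2
        assert genotype_r2(g1, g2) == pytest.approx(expected)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            genotype_r2(np.zeros(3, dtype=np.int8), np.zeros(4, dtype=np.int8))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from([0, 1, 2]),
                              st.sampled_from([0, 1, 2])),
                    min_size=2, max_size=30))
    def test_r2_in_unit_interval(self, pairs):
        g1 = np.array([p[0] for p in pairs], dtype=np.int8)
        g2 = np.array([p[1] for p in pairs], dtype=np.int8)
        r2 = genotype_r2(g1, g2)
        if r2 is not UNDEFINED:
            assert 0.0 <= r2 <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# haplotype r2 against the published three-SNP worked example
# ---------------------------------------------------------------------------

class TestHaplotypeR2:
    @pytest.mark.parametrize(
        "column,target,expected,tol",
        [
            ("combined", "anchor", 0.199, 0.006),
            ("controls", "anchor", 0.255, 0.006),
            ("combined", "partner", 0.002, 0.006),
            ("controls", "partner", 0.004, 0.003),
            ("combined", "combination", 0.374, 0.006),
            ("controls", "combination", 0.438, 0.006),
        ],
    )
    def test_malaria_haplotype_correlations(self, column, target, expected, tol):
        """Published expected haplotype counts reproduce the published r2."""
        fx = table1_fixture()
        counts = (
            fx["case_counts"] + fx["control_counts"]
            if column == "combined" else fx["control_counts"]
        )
        y = {
            "anchor": fx["anchor_is_C"],
            "partner": fx["partner_is_C"],
            "combination": fx["anchor_is_C"] + fx["partner_is_C"],
        }[target]
        r2 = haplotype_r2_from_counts(counts, fx["causal_is_A"], y)
        assert r2 == pytest.approx(expected, abs=tol)

    def test_zero_variance_undefined(self):
        w = np.array([1.0, 1.0])
        assert haplotype_r2_from_counts(w, np.array([1.0, 1.0]),
                                        np.array([0.0, 1.0])) is UNDEFINED

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            haplotype_r2_from_counts(np.zeros(4), np.arange(4), np.arange(4))


# ---------------------------------------------------------------------------
# partition sampler
# ---------------------------------------------------------------------------

class TestPartitionSampler:
    def test_sums_to_one_nonnegative(self, rng):
        draws = sample_haplotype_partition(rng, size=10_000)
        assert draws.shape == (10_000, 8)
        assert np.all(draws >= 0.0)
        np.testing.assert_allclose(draws.sum(axis=1), 1.0, atol=1e-12)

    def test_marginal_means_exchangeable(self, rng):
        # each fixed haplotype is equally likely to be drawn at any step,
        # so its marginal mean frequency is 1/8
        draws = sample_haplotype_partition(rng, size=100_000)
        np.testing.assert_allclose(draws.mean(axis=0), 1 / 8, atol=0.004)

    def test_first_assigned_frequency_uniform(self, rng):
        draws, order = sample_haplotype_partition(rng, size=100_000,
                                                  return_order=True)
        first = np.take_along_axis(draws, order[:, :1], axis=1)[:, 0]
        assert first.mean() == pytest.approx(0.5, abs=0.01)
        assert first.var() == pytest.approx(1 / 12, abs=0.005)


# ---------------------------------------------------------------------------
# case/control simulation
# ---------------------------------------------------------------------------

def _random_model(rng, penetrances=(0.01, 0.015, 0.0225)):
    return HaplotypeDiseaseModel(sample_haplotype_partition(rng), penetrances)


class TestSimulateCaseControl:
    def test_shape_and_exact_counts(self, rng):
        model = _random_model(rng)
        geno, pheno = simulate_case_control(model, 1000, 1000, rng)
        assert geno.shape == (2000, 3)
        assert pheno.sum() == 1000
        assert set(np.unique(geno)) <= {0, 1, 2}

    def test_flat_penetrance_gives_population_frequency(self, rng):
        model = _random_model(rng, penetrances=(0.05, 0.05, 0.05))
        geno, pheno = simulate_case_control(model, 4000, 4000, rng)
        # anchor-dosage index varies slowest in the 27-triple enumeration
        pop_freq = model.triple_probabilities() @ (
            np.repeat(np.arange(3), 9) / 2.0
        )
        case_freq = geno[pheno == 1, 0].mean() / 2.0
        assert case_freq == pytest.approx(pop_freq, abs=0.02)

    def test_case_distribution_matches_conditional_oracle(self, rng):
        # empirical case triple distribution vs analytic freq x penetrance
        model = _random_model(rng)
        case9, _, _ = model.conditional_cell_distributions()
        geno, pheno = simulate_case_control(model, 20_000, 10, rng)
        cells = geno[pheno == 1, 0] * 3 + geno[pheno == 1, 2]
        emp = np.bincount(cells, minlength=9) / 20_000
        np.testing.assert_allclose(emp, case9, atol=0.01)

    def test_degenerate_penetrances_rejected(self, rng):
        freqs = sample_haplotype_partition(rng)
        with pytest.raises(ValueError, match="degenerate|penetrances"):
            model = HaplotypeDiseaseModel(freqs, (0.0, 0.0, 0.0))
            simulate_case_control(model, 10, 10, rng)


# ---------------------------------------------------------------------------
# curve construction and score
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_curve():
    cfg = MetricConstructionConfig(n_replicates=30_000, seed=7)
    return run_metric_construction(cfg)


class TestMetricCurve:
    def test_anchored_and_scaled(self, small_curve):
        assert small_curve.evaluate(0.0) == pytest.approx(0.0, abs=1e-9)
        assert small_curve.evaluate(1.0) == pytest.approx(0.0, abs=1e-9)
        grid = np.arange(0.0, 1.0005, 1e-3)
        vals = small_curve.evaluate(grid)
        assert np.all((vals >= 0.0) & (vals <= 100.0))
        assert vals.max() == pytest.approx(100.0, abs=1e-6)

    def test_bit_reproducible(self):
        cfg = MetricConstructionConfig(n_replicates=5_000, seed=99)
        c1 = run_metric_construction(cfg)
        c2 = run_metric_construction(cfg)
        assert c1.to_dict() == c2.to_dict()

    def test_serialization_roundtrip(self, small_curve, tmp_path):
        path = tmp_path / "curve.json"
        small_curve.save(path)
        back = MetricCurve.load(path)
        grid = np.linspace(0, 1, 101)
        np.testing.assert_allclose(back.evaluate(grid),
                                   small_curve.evaluate(grid))

    def test_lower_top_fraction_does_not_raise_argmax(self):
        # a stricter "top differences" threshold shifts the peak toward
        # lower correlations, never higher (within one bin width)
        base = run_metric_construction(
            MetricConstructionConfig(n_replicates=100_000, seed=11)
        )
        strict = run_metric_construction(
            MetricConstructionConfig(n_replicates=100_000, seed=11,
                                     top_fraction=0.002)
        )
        assert strict.argmax() <= base.argmax() + 0.05

    def test_score_clamps_and_handles_undefined(self, small_curve):
        assert score(small_curve, UNDEFINED) == 0.0
        assert score(small_curve, 0.0) == pytest.approx(0.0, abs=1e-9)
        assert score(small_curve, small_curve.argmax()) == pytest.approx(
            100.0, abs=1e-6
        )

    def test_construction_penetrance_variants_defined(self):
        assert set(MODEL_PENETRANCES) == {
            "multiplicative", "dominant", "recessive"
        }
        for p0, p1, p2 in MODEL_PENETRANCES.values():
            assert 0 < p0 <= p1 <= p2 < 1
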