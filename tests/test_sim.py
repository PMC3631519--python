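"""Synthetic-data generator: drift model, individuals, pedigrees, degradation."""

from __future__ import annotations

import numpy as np
import pytest

from forensnp import sim
from forensnp.qc import qc_call_rate


def hudson_fst(g1: np.ndarray, g2: np.ndarray) -> float:
    """Hudson FST (ratio of averages) from two diploid dosage matrices.

    Independent oracle: numerator (p1-p2)^2 minus within-population sampling
    corrections, denominator p1(1-p2) + p2(1-p1), both averaged over markers
    before the ratio.
    """
    n1, n2 = 2 * g1.shape[0], 2 * g2.shape[0]
    p1, p2 = g1.mean(axis=0) / 2.0, g2.mean(axis=0) / 2.0
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())


def split_by_pop(ref: sim.SimulatedReference, pop: str) -> np.ndarray:
    mask = ref.genotypes.metadata["population"] == pop
    auto = ref.marker_panel.class_mask(["autosomal"])
    return ref.genotypes.dosage[np.asarray(mask)][:, auto]


class TestSimConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            sim.SimConfig(n_populations=1)
        with pytest.raises(ValueError):
            sim.SimConfig(n_populations=2, drift=(0.0, 0.1))
        with pytest.raises(ValueError):
            sim.SimConfig(n_populations=2, drift=(0.1, 1.0))
        with pytest.raises(ValueError):
            sim.SimConfig(n_autosomal=-1)
        with pytest.raises(ValueError):
            sim.SimConfig(ancestral_freq_range=(0.01, 0.95))

    def test_default_drift_spans_continental_range(self):
        c = sim.SimConfig()
        assert len(c.drift) == 5
        assert min(c.drift) == pytest.approx(0.02)
        assert max(c.drift) == pytest.approx(0.15)


class TestReferencePanelSimulation:
    def test_no_drift_limit_collapses_population_differences(self):
        config = sim.SimConfig(
            n_populations=2, n_autosomal=2_000, n_x=0, n_y=0, n_mt=0,
            drift=(1e-4, 1e-4), seed=3,
        )
        ref = sim.simulate_reference_panel(config, n_per_pop=5)
        mean_diff = np.mean(np.abs(ref.freq_auto[0] - ref.freq_auto[1]))
        assert mean_diff < 0.01

    def test_hudson_fst_matches_monte_carlo_oracle(self):
        # Expected Balding-Nichols FST for two independently drifted
        # populations is F itself: E[(p1-p2)^2] / E[p1(1-p2)+p2(1-p1)]
        # = 2F pq / 2pq.  Frozen from a 2e5-replicate Monte-Carlo run
        # (observed 0.1994 at F = 0.2).
        config = sim.SimConfig(
            n_populations=2, n_autosomal=500, n_x=0, n_y=0, n_mt=0,
            drift=(0.2, 0.2), seed=17,
        )
        ref = sim.simulate_reference_panel(config, n_per_pop=50)
        fst = hudson_fst(split_by_pop(ref, "POP1"), split_by_pop(ref, "POP2"))
        assert fst == pytest.approx(0.20, abs=0.05)

    def test_identical_seeds_give_bit_identical_panels(self):
        config = sim.SimConfig(n_populations=2, n_autosomal=300, n_x=50, seed=9)
        a = sim.simulate_reference_panel(config, n_per_pop=5)
        b = sim.simulate_reference_panel(config, n_per_pop=5)
        assert a.genotypes.equals(b.genotypes)
        assert np.array_equal(a.freq_auto, b.freq_auto)
        assert np.array_equal(a.reference.loadings, b.reference.loadings)

    def test_increasing_drift_increases_fst(self):
        fsts = []
        for F in (0.02, 0.1, 0.3):
            config = sim.SimConfig(
                n_populations=2, n_autosomal=1_000, n_x=0, n_y=0, n_mt=0,
                drift=(F, F), seed=23,
            )
            ref = sim.simulate_reference_panel(config, n_per_pop=30)
            fsts.append(hudson_fst(split_by_pop(ref, "POP1"), split_by_pop(ref, "POP2")))
        assert fsts[0] < fsts[1] < fsts[2]

    def test_frequencies_clamped_away_from_fixation(self, ref3_small):
        for freqs in (ref3_small.freq_auto, ref3_small.freq_x):
            assert freqs.min() >= 0.001
            assert freqs.max() <= 0.999

    def test_too_few_reference_samples_rejected(self):
        with pytest.raises(ValueError, match="n_per_pop"):
            sim.simulate_reference_panel(sim.SimConfig(), n_per_pop=1)


class TestSimulateIndividual:
    def test_one_hot_q_reproduces_population_frequencies(self, ref3_small):
        # average empirical allele frequency over many markers tracks f_k
        g, state = sim.simulate_individual(ref3_small, [1, 0, 0], "female", seed=2)
        auto = ref3_small.marker_panel.class_mask(["autosomal"])
        emp = g.dosage[0, auto] / 2.0
        assert np.mean(emp - ref3_small.freq_auto[0]) == pytest.approx(0.0, abs=0.01)
        assert state.true_q[0] == 1.0

    def test_female_has_zero_y_calls_and_diploid_x(self, ref3_small):
        g, state = sim.simulate_individual(ref3_small, [0, 1, 0], "female", seed=4)
        y = g.dosage[0, ref3_small.marker_panel.class_mask(["Y"])]
        assert np.isnan(y).all()
        assert state.y_haplogroup is None
        x = g.dosage[0, ref3_small.marker_panel.class_mask(["X_specific"])]
        assert set(np.unique(x[np.isfinite(x)])) <= {0.0, 1.0, 2.0}

    def test_male_x_rendered_homozygous(self, ref3_small):
        g, state = sim.simulate_individual(ref3_small, [0, 0, 1], "male", seed=6)
        x = g.dosage[0, ref3_small.marker_panel.class_mask(["X_specific"])]
        assert set(np.unique(x[np.isfinite(x)])) <= {0.0, 2.0}
        assert state.y_haplogroup is not None

    def test_off_simplex_q_rejected(self, ref3_small):
        with pytest.raises(ValueError, match="simplex"):
            sim.simulate_individual(ref3_small, [0.6, 0.6, 0.0], "male", seed=1)

    def test_true_state_invariants_enforced(self):
        with pytest.raises(ValueError):
            sim.TrueState("s", np.array([0.5, 0.4]), ("A", "B"), "male")
        with pytest.raises(ValueError):
            sim.TrueState(
                "s", np.array([1.0]), ("A",), "female", y_haplogroup="Y-A1"
            )


class TestRelativePairs:
    def test_parent_offspring_shares_an_allele_everywhere(self, ref3_small):
        g, ta, tb = sim.simulate_relative_pair(ref3_small, "POP1", 1, seed=31)
        auto = ref3_small.marker_panel.class_mask(["autosomal"])
        a, b = g.dosage[0, auto], g.dosage[1, auto]
        # opposite homozygotes are impossible when one allele is IBD
        assert np.max(np.abs(a - b)) <= 1
        assert ta.realised_pi == pytest.approx(0.5)
        assert ta.pedigree_degree == 1

    def test_realised_sharing_tracks_expectation(self, ref3_small):
        for degree, expected in sim.DEGREE_EXPECTED_PI.items():
            pis = [
                sim.simulate_relative_pair(ref3_small, "POP2", degree, seed=100 + s)[1].realised_pi
                for s in range(10)
            ]
            assert np.mean(pis) == pytest.approx(expected, abs=0.05)

    def test_unrelated_pair_shares_nothing_by_descent(self, ref3_small):
        _, ta, _ = sim.simulate_relative_pair(ref3_small, "POP1", "unrelated", seed=8)
        assert ta.realised_pi == 0.0
        assert ta.pedigree_degree is None

    def test_invalid_degree_rejected(self, ref3_small):
        with pytest.raises(ValueError):
            sim.simulate_relative_pair(ref3_small, "POP1", 5, seed=1)
        with pytest.raises(ValueError, match="does not realise"):
            sim.simulate_relative_pair(
                ref3_small, "POP1", 2, seed=1, relationship="first_cousin"
            )

    def test_study_cohort_composition(self, ref2_20k):
        cohort, expected = sim.simulate_relatedness_study(ref2_20k, "POP1", seed=42)
        assert cohort.n_samples == 81
        counts = {}
        for d in expected.values():
            counts[d] = counts.get(d, 0) + 1
        assert counts == {
            "first": 27,
            "second": 10,
            "third": 3,
            "fourth": 1,
            "unrelated": 3_199,
        }


class TestQualityLoss:
    def test_zero_rates_return_identical_matrix(self, ref3_small):
        g, _ = sim.simulate_individual(ref3_small, [1, 0, 0], "male", seed=12)
        out = sim.apply_quality_loss(g, 0.0, 0.0, seed=1)
        assert out.equals(g)

    def test_moderate_missingness_fails_qc_gate(self, ref3_small):
        g, _ = sim.simulate_individual(ref3_small, [1, 0, 0], "female", seed=13)
        failures = 0
        for rep in range(50):
            degraded = sim.apply_quality_loss(g, 0.12, 0.0, seed=1000 + rep)
            failures += int(not qc_call_rate(degraded).passed.iloc[0])
        assert failures >= 45  # >= 90 % of replicates over the 10 % gate

    def test_rates_respected_and_mask_updated(self, ref3_small):
        g, _ = sim.simulate_individual(ref3_small, [0, 1, 0], "female", seed=14)
        degraded = sim.apply_quality_loss(g, 0.3, 0.1, seed=2)
        frac_missing = np.isnan(degraded.dosage).mean()
        base_missing = np.isnan(g.dosage).mean()
        expected = base_missing + (1 - base_missing) * 0.3
        assert frac_missing == pytest.approx(expected, abs=0.03)
        # surviving calls still valid dosages
        vals = degraded.dosage[np.isfinite(degraded.dosage)]
        assert set(np.unique(vals)) <= {0.0, 1.0, 2.0}

    def test_haploid_errors_stay_haploid(self, ref3_small):
        g, _ = sim.simulate_individual(ref3_small, [1, 0, 0], "male", seed=15)
        degraded = sim.apply_quality_loss(g, 0.0, 0.5, seed=3)
        hap = ref3_small.marker_panel.haploid_mask
        vals = degraded.dosage[0, hap]
        assert np.nanmax(vals) <= 1

    def test_out_of_range_rates_rejected(self, ref3_small):
        g, _ = sim.simulate_individual(ref3_small, [1, 0, 0], "male", seed=16)
        with pytest.raises(ValueError):
            sim.apply_quality_loss(g, 1.5, 0.0, seed=1)
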