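"""PCA reference space, nearest-centroid assignment and supervised admixture."""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np
import pytest

from forensnp import sim
from forensnp.ancestry import (
    MULTIPLE_GROUPS,
    ReferencePanel,
    admixture_loglik,
    analyse_sample,
    assign_quantitative,
    estimate_admixture,
    fit_reference,
    group_summary,
    project_and_assign,
)
from forensnp.panel import GenotypeMatrix, MarkerPanel


def grid_search_q(x: np.ndarray, freqs: np.ndarray, step: float = 0.01) -> np.ndarray:
    """Brute-force oracle: best q on a simplex grid for K = 3."""
    best_q, best_ll = None, -np.inf
    for i in range(int(1 / step) + 1):
        q1 = i * step
        for j in range(int((1 - q1) / step) + 1):
            q2 = j * step
            q = np.array([q1, q2, 1.0 - q1 - q2])
            ll = admixture_loglik(q, x, freqs)
            if ll > best_ll:
                best_q, best_ll = q, ll
    return best_q


class TestFitReference:
    def test_diverged_pops_separate_on_pc1(self):
        config = sim.SimConfig(
            n_populations=2, n_autosomal=1_000, n_x=0, n_y=0, n_mt=0,
            drift=(0.3, 0.3), seed=41,
        )
        ref = sim.simulate_reference_panel(config, n_per_pop=25)
        fitted = fit_reference(ref.genotypes)
        mask = ref.marker_panel.class_mask(["autosomal"])
        pops = np.asarray(ref.genotypes.metadata["population"])
        coords = np.array(
            [
                project_and_assign(ref.genotypes, s, fitted)[0]
                for s in ref.genotypes.sample_ids
            ]
        )
        pc1_a = coords[pops == "POP1", 0]
        pc1_b = coords[pops == "POP2", 0]
        assert max(pc1_a.max(), pc1_b.max()) > min(pc1_a.min(), pc1_b.min())
        assert pc1_a.max() < pc1_b.min() or pc1_b.max() < pc1_a.min()

    def test_projection_self_consistent_for_reference_samples(self, ref3_small):
        g = ref3_small.genotypes
        fitted = fit_reference(g)
        # recompute the fit-time scores directly
        idx = {m: i for i, m in enumerate(g.panel.marker_ids)}
        cols = [idx[m] for m in fitted.marker_ids]
        z = (g.dosage[:, cols] - fitted.center) / fitted.scale
        z = np.where(np.isnan(z), 0.0, z)
        scores = z @ fitted.loadings
        for i, s in enumerate(g.sample_ids[:10]):
            coords, _, _ = project_and_assign(g, s, fitted)
            assert np.allclose(coords, scores[i], atol=1e-8)

    def test_five_populations_cluster_around_own_centroids(self, ref5_20k):
        g = ref5_20k.genotypes
        fitted = ref5_20k.reference
        pops = list(g.metadata["population"])
        hits = sum(
            project_and_assign(g, s, fitted)[1] == p
            for s, p in zip(g.sample_ids, pops)
        )
        assert hits / g.n_samples >= 0.95

    def test_requires_two_populations_two_samples_each(self, ref3_small):
        g = ref3_small.genotypes.subset_samples(ref3_small.genotypes.sample_ids[:5])
        with pytest.raises(ValueError, match="two"):
            fit_reference(g, labels=["A"] * 5)
        with pytest.raises(ValueError, match="<2"):
            fit_reference(g, labels=["A", "A", "B", "A", "A"])


class TestProjectAndAssign:
    @staticmethod
    def tiny_panel() -> ReferencePanel:
        return ReferencePanel(
            labels=["A", "B"],
            marker_ids=np.array(["m1", "m2"]),
            freqs=np.array([[0.9, 0.9], [0.1, 0.1]]),
            center=np.array([1.0, 1.0]),
            scale=np.array([1.0, 1.0]),
            loadings=np.eye(2),
            centroids=np.array([[1.0, 1.0], [-1.0, -1.0]]),
        )

    def test_sample_at_centroid_has_distance_zero(self):
        panel = self.tiny_panel()
        g = GenotypeMatrix(
            sample_ids=["s"],
            panel=MarkerPanel.from_arrays(["m1", "m2"], ["autosomal"] * 2),
            dosage=np.array([[2.0, 2.0]]),  # z = (1, 1) = centroid of A
        )
        coords, group, dist = project_and_assign(g, "s", panel)
        assert group == "A"
        assert dist == pytest.approx(0.0, abs=1e-12)

    def test_equidistant_tie_breaks_by_label_order(self, caplog):
        panel = self.tiny_panel()
        g = GenotypeMatrix(
            sample_ids=["s"],
            panel=MarkerPanel.from_arrays(["m1", "m2"], ["autosomal"] * 2),
            dosage=np.array([[1.0, 1.0]]),  # z = (0, 0), equidistant
        )
        with caplog.at_level("WARNING", logger="forensnp.ancestry"):
            _, group, _ = project_and_assign(g, "s", panel)
        assert group == "A"
        assert any("equidistant" in r.message for r in caplog.records)

    def test_insufficient_overlap_rejected(self):
        panel = self.tiny_panel()
        g = GenotypeMatrix(
            sample_ids=["s"],
            panel=MarkerPanel.from_arrays(["m1", "m2"], ["autosomal"] * 2),
            dosage=np.array([[np.nan, np.nan]]),
        )
        with pytest.raises(ValueError, match="panel markers"):
            project_and_assign(g, "s", panel)

    def test_admixed_sample_lies_between_parental_centroids(self, ref5_20k):
        g, _ = sim.simulate_individual(
            ref5_20k, [0.5, 0.5, 0, 0, 0], "female", seed=51, sample_id="adm"
        )
        coords, _, _ = project_and_assign(g, "adm", ref5_20k.reference)
        cents = ref5_20k.reference.centroids
        d = np.linalg.norm(cents - coords, axis=1)
        parents = {
            ref5_20k.reference.labels.index("AFR"),
            ref5_20k.reference.labels.index("EUR"),
        }
        assert set(np.argsort(d)[:2]) == parents


class TestEstimateAdmixture:
    def test_degenerate_single_marker_likelihood(self):
        panel = ReferencePanel(
            labels=["A", "B"],
            marker_ids=np.array(["m1"]),
            freqs=np.array([[0.999], [0.001]]),
            center=np.array([1.0]),
            scale=np.array([0.7]),
            loadings=np.array([[1.0]]),
            centroids=np.array([[1.0], [-1.0]]),
        )
        q, _, _ = estimate_admixture(np.array([2.0]), panel)
        assert q[0] > 0.99

    def test_em_matches_grid_search_oracle(self, ref3_small):
        rng = np.random.default_rng(61)
        freqs = ref3_small.reference.freqs[:, :20]
        panel = replace(
            ref3_small.reference,
            marker_ids=ref3_small.reference.marker_ids[:20],
            freqs=freqs,
            center=ref3_small.reference.center[:20],
            scale=ref3_small.reference.scale[:20],
            loadings=ref3_small.reference.loadings[:20],
        )
        true_q = np.array([0.6, 0.3, 0.1])
        x = rng.binomial(2, true_q @ freqs).astype(float)
        q_em, _, _ = estimate_admixture(x, panel, tol=1e-10, max_iter=5000)
        q_grid = grid_search_q(x, freqs)
        assert np.max(np.abs(q_em - q_grid)) <= 0.02

    def test_half_half_admixture_recovered_at_20k_markers(self, ref5_20k):
        g, _ = sim.simulate_individual(
            ref5_20k, [0.5, 0.5, 0, 0, 0], "male", seed=52, sample_id="adm"
        )
        q, _, _ = estimate_admixture(g, ref5_20k.reference, sample_id="adm")
        truth = np.zeros(5)
        truth[ref5_20k.reference.labels.index("AFR")] = 0.5
        truth[ref5_20k.reference.labels.index("EUR")] = 0.5
        assert np.max(np.abs(q - truth)) <= 0.05

    def test_likelihood_monotone_nondecreasing(self, ref3_small):
        rng = np.random.default_rng(62)
        for _ in range(3):
            q_true = rng.dirichlet(np.ones(3))
            x = rng.binomial(2, q_true @ ref3_small.reference.freqs).astype(float)
            _, _, _, trace = estimate_admixture(
                x, ref3_small.reference, return_trace=True
            )
            diffs = np.diff(trace)
            assert np.all(diffs >= -1e-9)

    def test_q_invariant_to_marker_order_and_duplication(self, ref3_small):
        rng = np.random.default_rng(63)
        panel = ref3_small.reference
        x = rng.binomial(2, np.array([0.3, 0.7, 0.0]) @ panel.freqs).astype(float)
        q0, _, _ = estimate_admixture(x, panel)
        perm = rng.permutation(len(x))
        panel_perm = replace(
            panel,
            marker_ids=panel.marker_ids[perm],
            freqs=panel.freqs[:, perm],
            center=panel.center[perm],
            scale=panel.scale[perm],
            loadings=panel.loadings[perm],
        )
        q1, _, _ = estimate_admixture(x[perm], panel_perm)
        panel_dup = replace(
            panel,
            marker_ids=np.concatenate([panel.marker_ids, panel.marker_ids]),
            freqs=np.hstack([panel.freqs, panel.freqs]),
            center=np.concatenate([panel.center, panel.center]),
            scale=np.concatenate([panel.scale, panel.scale]),
            loadings=np.vstack([panel.loadings, panel.loadings]),
        )
        q2, _, _ = estimate_admixture(np.concatenate([x, x]), panel_dup)
        assert np.allclose(q0, q1, atol=1e-6)
        assert np.allclose(q0, q2, atol=1e-6)

    def test_missing_markers_skipped(self, ref3_small):
        rng = np.random.default_rng(64)
        panel = ref3_small.reference
        x = rng.binomial(2, panel.freqs[0]).astype(float)
        x[rng.random(len(x)) < 0.3] = np.nan
        q, _, _ = estimate_admixture(x, panel)
        assert int(np.argmax(q)) == 0


class TestAssignment:
    def test_threshold_is_strict(self):
        labels = ["A", "B", "C", "D", "E"]
        assert assign_quantitative([0.71, 0.29, 0, 0, 0], labels) == "A"
        assert assign_quantitative([0.70, 0.30, 0, 0, 0], labels) == MULTIPLE_GROUPS
        assert assign_quantitative([0.2] * 5, labels) == MULTIPLE_GROUPS

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            assign_quantitative([0.8, 0.8], ["A", "B"])

    def test_pure_samples_agree_across_both_routes(self, ref5_20k):
        """Distance-based and quantitative assignments coincide on
        pure-population individuals."""
        g = ref5_20k.genotypes
        agree = total = 0
        for s in g.sample_ids[::3]:
            r = analyse_sample(g, s, ref5_20k.reference)
            total += 1
            agree += int(
                r.nearest_group == r.assignment != MULTIPLE_GROUPS
            )
        assert agree / total >= 0.99

    def test_reference_self_assignment_rate(self, ref5_20k):
        """Quantitative 0.70-rule self-assignment per population."""
        g = ref5_20k.genotypes
        pops = np.asarray(g.metadata["population"])
        for pop in ref5_20k.labels:
            ids = [s for s, p in zip(g.sample_ids, pops) if p == pop][::3]
            hits = 0
            for s in ids:
                q, _, _ = estimate_admixture(g, ref5_20k.reference, sample_id=s)
                hits += int(
                    assign_quantitative(q, ref5_20k.reference.labels) == pop
                )
            assert hits / len(ids) >= 0.95


class TestGroupSummary:
    def test_identical_qs_give_zero_width_boxes(self):
        q = np.tile([0.7, 0.3], (8, 1))
        out = group_summary(q, ["AFR", "EUR"], ["c"] * 8)
        assert (out["q1"] == out["q3"]).all()
        assert (out["whisker_low"] == out["whisker_high"]).all()

    def test_admixed_cohort_medians_sit_between_parents(self):
        rng = np.random.default_rng(71)
        q_afr = np.clip(rng.normal(0.6, 0.05, 24), 0, 1)
        q = np.column_stack([q_afr, 1 - q_afr])
        out = group_summary(q, ["AFR", "EUR"], ["ethiopian_like"] * 24)
        med = out.set_index("component")["median"]
        assert 0.5 <= med["AFR"] <= 0.7

    def test_intermediate_origin_indistinguishable_from_mixed_race(self):
        # two cohorts with the same mean ancestry composition produce
        # essentially the same box summaries: the method cannot tell a
        # geographically intermediate population from recent admixture
        rng = np.random.default_rng(72)
        a = np.clip(rng.normal(0.5, 0.03, 40), 0, 1)
        b = np.clip(rng.normal(0.5, 0.03, 40), 0, 1)
        q = np.column_stack([np.concatenate([a, b]), 1 - np.concatenate([a, b])])
        cohorts = ["intermediate_origin"] * 40 + ["mixed_race"] * 40
        out = group_summary(q, ["EAS", "EUR"], cohorts)
        med = out.pivot(index="cohort", columns="component", values="median")
        assert abs(med.loc["intermediate_origin", "EAS"] - med.loc["mixed_race", "EAS"]) < 0.05
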