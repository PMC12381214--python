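"""GMM pathway classification: transform, model selection, reclassification."""

import numpy as np
import pandas as pd
import pytest

from catchbond import (
    assign_pathways,
    fit_pathway_gmm,
    pathway_proportions,
    preprocess_forces,
    reclassify_fourth_component,
)
from catchbond.pathways import GMMResult


def trimodal(n=600, seed=0, means=(35.0, 110.0, 420.0), sds=(8.0, 22.0, 70.0),
             weights=(0.4, 0.35, 0.25)):
    rng = np.random.default_rng(seed)
    comp = rng.choice(3, size=n, p=weights)
    forces = rng.normal(np.array(means)[comp], np.array(sds)[comp])
    return np.clip(forces, 1.0, None), comp


class TestPreprocess:
    def test_singleton_maps_to_zero(self):
        z, tr = preprocess_forces([4.0])
        assert z[0] == 0.0
        assert tr.mean == pytest.approx(2.0)  # sqrt applied first

    def test_standardisation_identity(self):
        rng = np.random.default_rng(1)
        z, _ = preprocess_forces(rng.uniform(10, 500, 400))
        assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
        assert np.var(z) == pytest.approx(1.0, abs=1e-12)

    def test_inverse_round_trip(self):
        forces = np.array([20.0, 55.0, 130.0, 400.0])
        z, tr = preprocess_forces(forces)
        assert np.allclose(tr.inverse(z), forces, rtol=1e-9)

    def test_nonpositive_forces_rejected(self):
        with pytest.raises(ValueError):
            preprocess_forces([10.0, -1.0])


class TestModelSelection:
    def test_trimodal_selects_three_components_with_weights(self):
        """Across 10 seeds: 3 components selected, weights within 0.05."""
        for seed in range(10):
            forces, _ = trimodal(seed=seed)
            result = fit_pathway_gmm(forces, seed=seed)
            assert result.n_components == 3
            got = np.sort(result.weights)
            assert np.allclose(np.sort(got), sorted([0.4, 0.35, 0.25]), atol=0.05)

    def test_unimodal_selects_one_component(self):
        rng = np.random.default_rng(3)
        forces = np.clip(rng.normal(80.0, 12.0, 500), 1.0, None)
        assert fit_pathway_gmm(forces, seed=0).n_components == 1

    def test_two_modes_recovered_within_5_percent(self):
        rng = np.random.default_rng(4)
        forces = np.concatenate(
            [rng.normal(40.0, 5.0, 300), rng.normal(300.0, 30.0, 300)]
        )
        result = fit_pathway_gmm(np.clip(forces, 1.0, None), seed=0)
        assert result.n_components == 2
        means = np.sort(result.component_means_pN())
        assert means[0] == pytest.approx(40.0, rel=0.05)
        assert means[1] == pytest.approx(300.0, rel=0.05)

    def test_too_few_records_refused(self):
        with pytest.raises(ValueError):
            fit_pathway_gmm(np.full(10, 50.0))

    def test_classification_accuracy_well_separated(self):
        forces, comp = trimodal(n=900, seed=7)
        result = fit_pathway_gmm(forces, seed=0)
        labels = assign_pathways(result)["pathway"].to_numpy()
        truth = np.array(["P0", "P1", "P2"])[comp]
        assert np.mean(labels == truth) >= 0.95


class TestReclassification:
    def test_three_component_result_unchanged(self):
        forces, _ = trimodal(seed=1)
        result = fit_pathway_gmm(forces, seed=0)
        assert reclassify_fourth_component(result) is result

    def test_nested_fourth_component_folds_into_parent(self):
        """A minor component fully nested in the middle one: its records all
        become P1 after reclassification."""
        n = 200
        resp = np.zeros((n, 4))
        resp[:150, 1] = 1.0  # parent component
        resp[150:, 3] = 0.6  # minor nested component
        resp[150:, 1] = 0.4
        resp[:50, 0] = resp[:50, 1]
        resp[:50, 1] = 0.0
        result = GMMResult(
            n_components=4,
            weights=np.array([0.25, 0.5, 0.2, 0.05]),
            means=np.array([-1.5, 0.0, 1.5, 0.05]),
            variances=np.array([0.1, 0.2, 0.1, 0.15]),
            responsibilities=resp,
            transform=None,
            scores={},
        )
        out = reclassify_fourth_component(result)
        assert out.n_components == 3
        labels = assign_pathways(out)["pathway"]
        assert (labels.iloc[150:] == "P1").all()

    def test_four_way_fit_of_trimodal_data_recovers_truth(self):
        forces, comp = trimodal(n=900, seed=5)
        four = fit_pathway_gmm(forces, candidate_components=(4,), seed=0)
        out = reclassify_fourth_component(four)
        assert out.n_components == 3
        labels = assign_pathways(out)["pathway"].to_numpy()
        truth = np.array(["P0", "P1", "P2"])[comp]
        assert np.mean(labels == truth) >= 0.95


class TestProportions:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["pathway", "pulling_speed_nm_s", "experiment_id"])

    def test_single_experiment_all_p0(self):
        df = self.frame([("P0", 800, "e1")] * 10)
        out = pathway_proportions(df)
        assert out["proportion"].iloc[0] == 1.0
        assert np.isnan(out["sem"].iloc[0])

    def test_two_experiment_sem_closed_form(self):
        rows = [("P0", 800, "e1")] * 6 + [("P1", 800, "e1")] * 4
        rows += [("P0", 800, "e2")] * 8 + [("P1", 800, "e2")] * 2
        out = pathway_proportions(self.frame(rows))
        p0 = out[out["pathway"] == "P0"].iloc[0]
        assert p0["proportion"] == pytest.approx(0.7)
        assert p0["sem"] == pytest.approx(0.1)

    def test_proportions_sum_to_one_per_speed(self):
        rng = np.random.default_rng(0)
        rows = [
            (rng.choice(["P0", "P1", "P2"]), speed, f"e{e}")
            for speed in (800, 6400) for e in range(3) for _ in range(40)
        ]
        out = pathway_proportions(self.frame(rows))
        sums = out.groupby("pulling_speed_nm_s")["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)
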