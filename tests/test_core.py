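"""Orthogonal projection, complex-community prediction, relative change,
modulation, and graph exports."""

import numpy as np
import pytest

import networkx as nx

from miia import (
    CoefficientMatrix,
    InconsistentConstraintError,
    MIIA,
    UnidentifiableError,
    build_binary_set,
    membership_key,
    modulation,
    predict_community,
    prediction_coverage,
    project_row,
    relative_change,
)
from miia.core import matrices_from_frame, matrices_to_frame
from miia.io import matrix_to_edgelist, matrix_to_graph, write_graphml
from conftest import build_observation_set


def random_instance(rng, n_partners):
    b = rng.uniform(-2, 2, size=n_partners)
    x = rng.uniform(1e-6, 10, size=n_partners)
    d = rng.uniform(-10, 10)
    return b, x, d


class TestProjectRow:
    def test_two_partner_example(self):
        b, lam = project_row([1.0, 0.0], [2.0, 1.0], 4.0)
        assert b == pytest.approx([1.8, 0.4])
        assert lam == pytest.approx(0.4)

    def test_on_hyperplane_unchanged(self):
        b, lam = project_row([2.0, 0.0], [1.0, 1.0], 2.0)
        assert b.tolist() == [2.0, 0.0]
        assert lam == 0.0

    def test_single_partner_unique_solution(self):
        b, _ = project_row([0.5], [4.0], 6.0)
        assert b == pytest.approx([1.5])

    def test_degenerate_vacuous_constraint_warns(self):
        with pytest.warns(UserWarning, match="vacuous"):
            b, lam = project_row([1.0, -1.0], [0.0, 0.0], 0.0)
        assert b.tolist() == [1.0, -1.0] and lam == 0.0

    def test_degenerate_inconsistent_constraint_raises(self):
        with pytest.raises(InconsistentConstraintError):
            project_row([1.0], [0.0], 3.0)

    def test_constraint_satisfied_and_optimal(self):
        """Projection lands on the hyperplane and beats random feasible points."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            b0, x, d = random_instance(rng, int(rng.integers(2, 8)))
            b1, _ = project_row(b0, x, d)
            assert abs(b1 @ x - d) <= 1e-9 * max(1.0, abs(d))
            z = rng.normal(size=(200, x.size))
            feasible = z + np.outer((d - z @ x) / (x @ x), x)
            dists = np.linalg.norm(feasible - b0, axis=1)
            assert np.linalg.norm(b1 - b0) <= dists.min() + 1e-8

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            b0, x, d = random_instance(rng, 4)
            b1, _ = project_row(b0, x, d)
            b2, lam2 = project_row(b1, x, d)
            assert np.array_equal(b1, b2) and lam2 == 0.0

    def test_abundance_rescaling_keeps_constraint_exact(self):
        rng = np.random.default_rng(7)
        b0, x, d = random_instance(rng, 3)
        for c in (10.0, 1e4):
            b1, _ = project_row(b0, c * x, d)
            assert abs(b1 @ (c * x) - d) <= 1e-9 * max(1.0, abs(d))


class TestPredictCommunity:
    def test_size_two_passthrough(self, wang_dataset):
        obs = wang_dataset.observations
        bset = build_binary_set(obs)
        pair = obs.contexts(min_size=2, max_size=2)[0]
        cmat = predict_community(bset, obs, pair)
        i, j = cmat.members
        assert cmat.entries[(i, j)] == bset.value(i, j)

    def test_recovers_generated_truth(self, kato_dataset):
        obs = kato_dataset.observations
        bset = build_binary_set(obs)
        for key, truth in kato_dataset.truth_complex.items():
            cmat = predict_community(bset, obs, key)
            for pair, v in truth.entries.items():
                assert cmat.entries[pair] == pytest.approx(v, abs=1e-9)

    def test_strict_mode_names_missing_pairs(self, kato_obs):
        bset = build_binary_set(kato_obs)
        with pytest.raises(UnidentifiableError, match="<-CT"):
            predict_community(bset, kato_obs, "BA+CS+CT", strict=True)

    def test_original_form_requires_axenic_growth_of_focal(self, kato_obs):
        bset = build_binary_set(kato_obs, form="original")
        with pytest.raises(UnidentifiableError):
            predict_community(
                bset, kato_obs, "BA+CS+PT",
                assignments={p: 0.0 for p in bset.unidentifiable_pairs()},
            )

    def test_on_hyperplane_dataset_returns_binary_values(self):
        from miia import generate_dataset, make_fixture

        truth = {
            (i, j): v
            for (i, j), v in {
                ("JL", "LL"): 0.3, ("LL", "JL"): 0.2,
                ("JL", "LP"): -0.1, ("LP", "JL"): 0.15,
                ("LL", "LP"): 0.25, ("LP", "LL"): -0.2,
            }.items()
        }
        ds = generate_dataset(
            make_fixture("wang3"), truth, seed=5, complex_mode="steady_state"
        )
        obs = ds.observations
        bset = build_binary_set(obs)
        key = obs.contexts(min_size=3)[0]
        cmat = predict_community(bset, obs, key)
        for (i, j), v in cmat.entries.items():
            assert v == pytest.approx(bset.value(i, j), rel=1e-9)
        mod = modulation(bset, cmat)
        assert all(abs(m) <= 1e-9 for m in mod.entries.values())


class TestCoverage:
    def test_kato_scaled_coverage(self, kato_obs):
        bset = build_binary_set(kato_obs, form="scaled")
        coverage = prediction_coverage(bset, kato_obs)
        assert coverage[membership_key(("CS", "PT", "BA"))] == 1.0
        # communities needing a CT-influencer coefficient are not coverable
        assert coverage[membership_key(("CS", "CT", "PT"))] == 0.0
        assert coverage[membership_key(("BA", "CS", "CT", "PT"))] == 0.0

    def test_kato_original_coverage_reduced(self, kato_obs):
        bset = build_binary_set(kato_obs, form="original")
        coverage = prediction_coverage(bset, kato_obs)
        scaled = prediction_coverage(build_binary_set(kato_obs), kato_obs)
        key = membership_key(("CS", "PT", "BA"))
        assert coverage[key] < scaled[key]

    def test_all_growth_full_coverage(self, wang_obs):
        bset = build_binary_set(wang_obs)
        assert all(v == 1.0 for v in prediction_coverage(bset, wang_obs).values())


class TestRelativeChangeAndModulation:
    def test_examples(self):
        before = CoefficientMatrix("A+B+C", "scaled", {("A", "B"): 1.0, ("A", "C"): 2.0})
        after = CoefficientMatrix("A+B+C", "scaled", {("A", "B"): 1.8, ("A", "C"): 2.0})
        rel = relative_change(before, after)
        assert rel.entries[("A", "B")] == pytest.approx(0.8)
        assert rel.entries[("A", "C")] == 0.0

    def test_zero_denominator_flagged_not_dropped(self):
        before = CoefficientMatrix("A+B", "scaled", {("A", "B"): 0.0})
        after = CoefficientMatrix("A+B", "scaled", {("A", "B"): 1.0})
        rel = relative_change(before, after)
        assert ("A", "B") in rel.undefined
        assert np.isnan(rel.entries[("A", "B")])

    def test_form_equivalence_on_all_growth_data(self, wang_dataset):
        """Original and scaled pipelines give identical relative changes."""
        obs = wang_dataset.observations
        res_a = MIIA(obs, form="original").fit()
        res_b = MIIA(obs, form="scaled").fit()
        for key in res_a.complex:
            for pair, da in res_a.relative_changes[key].entries.items():
                db = res_b.relative_changes[key].entries[pair]
                assert da == pytest.approx(db, rel=1e-10, abs=1e-10)

    def test_modulation_weighted_identity(self, kato_dataset):
        """Sum_j m_ij x_j^C equals the residual d_i - b_B . x (algebra)."""
        obs = kato_dataset.observations
        bset = build_binary_set(obs)
        key = membership_key(("CS", "PT", "BA"))
        cmat = predict_community(bset, obs, key)
        mod = modulation(bset, cmat)
        for i in cmat.members:
            partners = [j for j in cmat.members if j != i]
            x = np.array([obs.abundance(j, key) for j in partners])
            b_row = np.array([bset.value(i, j) for j in partners])
            m_row = np.array([mod.entries[(i, j)] for j in partners])
            d_i = obs.abundance(i, key) - obs.abundance(i, (i,))
            assert m_row @ x == pytest.approx(d_i - b_row @ x, rel=1e-9, abs=1e-9)


class TestExports:
    def test_matrix_frame_roundtrip(self, kato_dataset):
        mats = list(kato_dataset.truth_complex.values())
        df = matrices_to_frame(mats)
        loaded = matrices_from_frame(df)
        for m in mats:
            assert loaded[m.context].entries == pytest.approx(m.entries)

    def test_edgelist_orientation(self):
        cmat = CoefficientMatrix("A+B", "scaled", {("A", "B"): -0.5, ("B", "A"): 0.2})
        edges = matrix_to_edgelist(cmat)
        row = edges[(edges.source == "B") & (edges.target == "A")].iloc[0]
        assert row.weight == -0.5 and row.sign == "negative"

    def test_graphml_roundtrip(self, tmp_path):
        cmat = CoefficientMatrix("A+B+C", "scaled", {("A", "B"): 1.5, ("C", "B"): 0.0})
        path = tmp_path / "net.graphml"
        write_graphml(cmat, path)
        graph = nx.read_graphml(path)
        assert graph.edges["B", "A"]["weight"] == 1.5
        assert graph.edges["B", "C"]["sign"] == "neutral"
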