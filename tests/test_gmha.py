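"""Graph attention autoencoder: features, equivariance, folds, training."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from scfc import GroundTruthMapping, SynthConfig, generate_cohort
from scfc.core import ConnectivityMatrix, ConnectomeError, Parcellation
from scfc.gmha import (
    CrossValResult,
    GmhaAutoencoder,
    LeakageError,
    build_node_features,
    export_latent,
    load_crossval,
    make_folds,
    normalized_fc_edges,
    predict_external,
    save_crossval,
    subject_graph,
    train_crossval,
)


def _ed_345():
    parc = Parcellation.generic(3)
    pts = np.array([[0, 0, 0], [3, 0, 0], [0, 4, 0]], float)
    return ConnectivityMatrix(values=squareform(pdist(pts)), kind="ED",
                              variant=None, parcellation=parc), parc


class TestNodeFeatures:
    def test_hand_computed_ed_statistics(self):
        ed, parc = _ed_345()
        sc = ConnectivityMatrix(
            values=np.array([[0, 1.0, 1], [1, 0, 1], [1, 1, 0]]),
            kind="SC", variant="FA", parcellation=parc,
        )
        feats = build_node_features(ed, sc, include_sc_row=False)
        # node 0 sees distances {3, 4}: mean 3.5, sample SD 0.7071, min 3;
        # features are z-scored across nodes, so check unscaled values
        n = 3
        off = ~np.eye(n, dtype=bool)
        dists = ed.values[off].reshape(n, n - 1)
        assert dists[0].mean() == pytest.approx(3.5)
        assert dists[0].std(ddof=1) == pytest.approx(0.70710678, abs=1e-6)
        assert dists[0].min() == 3.0
        # z-scored columns have mean ~0
        np.testing.assert_allclose(feats.mean(axis=0), 0.0, atol=1e-12)

    def test_equal_weight_complete_graph_constant_strength(self):
        ed, parc = _ed_345()
        w = 0.7
        sc = ConnectivityMatrix(
            values=w * (np.ones((3, 3)) - np.eye(3)),
            kind="SC", variant="FA", parcellation=parc,
        )
        feats = build_node_features(ed, sc, include_sc_row=False)
        # constant strength/degree columns z-score to exactly 0
        np.testing.assert_allclose(feats[:, 3], 0.0, atol=1e-12)
        np.testing.assert_allclose(feats[:, 4], 0.0, atol=1e-12)

    def test_sc_row_flag_controls_feature_count(self, small_cohort):
        ed = small_cohort.get("h001", "ED")
        sc = small_cohort.get("h001", "SC", "FA")
        n = small_cohort.parcellation.n
        assert build_node_features(ed, sc, include_sc_row=False).shape == (n, 5)
        assert build_node_features(ed, sc, include_sc_row=True).shape == (n, 5 + n)

    def test_too_few_nodes(self):
        parc = Parcellation.generic(2)
        m = ConnectivityMatrix(values=np.array([[0, 1.0], [1, 0]]), kind="ED",
                               variant=None, parcellation=parc)
        sc = ConnectivityMatrix(values=np.array([[0, 1.0], [1, 0]]), kind="SC",
                                variant="FA", parcellation=parc)
        with pytest.raises(ConnectomeError):
            build_node_features(m, sc)


class TestEncoderDecoder:
    @pytest.fixture()
    def tiny_graph(self, small_cohort):
        return subject_graph(small_cohort, "h001", "FA")

    def test_permutation_equivariance(self, small_cohort):
        """Relabeling nodes permutes latents and predictions consistently.

        Holds exactly for the intrinsic node features; the optional SC-row
        block indexes nodes by position and intentionally gives that up.
        """
        X, A = subject_graph(small_cohort, "h001", "FA", include_sc_row=False)
        n = A.shape[0]
        ae = GmhaAutoencoder(seed=0, epochs=1, batch_size=1)
        ae.fit([(X, A)], [np.zeros(n * (n - 1) // 2)])
        rng = np.random.default_rng(3)
        perm = rng.permutation(n)
        Xp = X[perm]
        Ap = A[perm][:, perm]
        Z = ae.encode(X, A)
        Zp = ae.encode(Xp, Ap)
        np.testing.assert_allclose(Zp, Z[perm], atol=1e-9)
        from scfc.core import matrix_from_edges
        pred = matrix_from_edges(ae.predict([(X, A)])[0], n)
        pred_p = matrix_from_edges(ae.predict([(Xp, Ap)])[0], n)
        np.testing.assert_allclose(pred_p, pred[perm][:, perm], atol=1e-9)

    def test_prediction_symmetric_zero_diagonal(self, tiny_graph):
        X, A = tiny_graph
        n = A.shape[0]
        ae = GmhaAutoencoder(seed=0, epochs=1, batch_size=1)
        ae.fit([(X, A)], [np.zeros(n * (n - 1) // 2)])
        from scfc.core import matrix_from_edges
        mat = matrix_from_edges(ae.predict([(X, A)])[0], n)
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)
        assert np.all(np.diag(mat) == 0)

    def test_isolated_node_survives_via_self_loop(self):
        parc = Parcellation.generic(4)
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1.0  # node 3 isolated
        X = np.random.default_rng(0).normal(size=(4, 6))
        ae = GmhaAutoencoder(seed=0, epochs=1, batch_size=1)
        ae.fit([(X, A)], [np.zeros(6)])
        assert np.all(np.isfinite(ae.encode(X, A)))

    def test_objective_definition(self, tiny_graph):
        X, A = tiny_graph
        n = A.shape[0]
        m = n * (n - 1) // 2
        ae = GmhaAutoencoder(seed=0, epochs=1, batch_size=1, gamma=0.0)
        ae.fit([(X, A)], [np.zeros(m)])
        target = ae.predict([(X, A)])[0]  # perfect reconstruction by definition
        assert ae.objective([(X, A)], [target]) == pytest.approx(0.0, abs=1e-15)
        ae.gamma = 0.01
        norm2 = sum(float((p.data**2).sum()) for p in ae.params_.values())
        assert ae.objective([(X, A)], [target]) == pytest.approx(0.01 * norm2)
        # hand MSE: two edges off by +/-0.1 -> mean squared error 0.01
        shifted = target.copy()
        shifted[0] += 0.1
        shifted[1] -= 0.1
        ae.gamma = 0.0
        assert ae.objective([(X, A)], [shifted]) == pytest.approx(0.02 / m)


class TestFolds:
    def test_sizes_partition_determinism(self):
        ids = [f"s{i}" for i in range(126)]
        split = make_folds(ids, k=5, seed=3)
        sizes = sorted(len(f) for f in split.folds)
        assert sizes == [25, 25, 25, 25, 26]
        flat = [sid for fold in split.folds for sid in fold]
        assert sorted(flat) == sorted(ids)
        again = make_folds(ids, k=5, seed=3)
        assert again.folds == split.folds

    def test_train_validation_disjoint_cover_development(self):
        split = make_folds([f"s{i}" for i in range(40)], k=5, seed=1)
        for i in range(5):
            tr, va, te = set(split.train[i]), set(split.validation[i]), set(split.folds[i])
            assert not (tr & va) and not (tr & te) and not (va & te)
            assert tr | va | te == {f"s{i}" for i in range(40)}

    def test_too_many_folds(self):
        with pytest.raises(ConnectomeError):
            make_folds(["a", "b"], k=5)


@pytest.fixture(scope="module")
def trained_tiny():
    """3-fold cross-validated training on a tiny noiseless cohort."""
    mapping = GroundTruthMapping(noise_sd=0.0, individuality_sd=0.0)
    cohort = generate_cohort(
        SynthConfig(seed=17, n_nodes=16, n_healthy=9, n_patients=2,
                    mapping=mapping)
    )
    result = train_crossval(
        cohort, "alpha", "FA", k=3, seed=2, subjects=cohort.healthy,
        epochs=15, batch_size=4,
    )
    return cohort, result


class TestTraining:
    def test_each_subject_scored_exactly_once(self, trained_tiny):
        cohort, result = trained_tiny
        assert sorted(result.records.subject) == sorted(
            s.id for s in cohort.healthy
        )

    def test_training_loss_mostly_decreases(self, trained_tiny):
        _, result = trained_tiny
        losses = [h["train_loss"] for h in result.models[0].history_]
        drops = np.diff(losses) <= 1e-9
        assert drops.mean() >= 0.8

    def test_deterministic_given_seed(self, trained_tiny):
        cohort, result = trained_tiny
        again = train_crossval(
            cohort, "alpha", "FA", k=3, seed=2, subjects=cohort.healthy,
            epochs=15, batch_size=4,
        )
        pd.testing.assert_frame_equal(result.records, again.records)

    def test_no_leakage_guard(self, trained_tiny):
        cohort, result = trained_tiny
        seen = result.fold_split.folds[0][0]
        with pytest.raises(LeakageError):
            predict_external(result, cohort, [seen])
        _, recs = predict_external(result, cohort, [seen], allow_seen=True)
        assert len(recs) == 1

    def test_patients_scored_by_fold_average(self, trained_tiny):
        cohort, result = trained_tiny
        patients = [s.id for s in cohort.patients]
        pfcs, recs = predict_external(result, cohort, patients)
        assert sorted(recs.subject) == sorted(patients)
        for sid in patients:
            mat = pfcs[sid].values
            np.testing.assert_allclose(mat, mat.T, atol=1e-12)

    def test_checkpoint_round_trip(self, trained_tiny, tmp_path):
        cohort, result = trained_tiny
        save_crossval(result, tmp_path / "model")
        back = load_crossval(tmp_path / "model")
        sid = result.fold_split.folds[0][0]
        g = subject_graph(cohort, sid, "FA")
        np.testing.assert_array_equal(
            result.models[0].predict([g])[0], back.models[0].predict([g])[0]
        )
        assert back.fold_split.folds == result.fold_split.folds

    def test_latent_export_shape_and_error_range(self, trained_tiny):
        cohort, result = trained_tiny
        table = export_latent(result, cohort)
        n = cohort.parcellation.n
        assert len(table) == len(cohort.subjects) * n
        assert table.prediction_error.between(0, 2).all()
        assert f"z{result.models[0].latent_dim - 1}" in table.columns

    def test_grid_search_selects_a_candidate(self):
        mapping = GroundTruthMapping(noise_sd=0.0, individuality_sd=0.0)
        cohort = generate_cohort(
            SynthConfig(seed=19, n_nodes=12, n_healthy=6, n_patients=0,
                        mapping=mapping)
        )
        result = train_crossval(
            cohort, "beta", "FA", k=2, seed=0, epochs=5, batch_size=4,
            grid={"latent_dim": [8, 16]},
        )
        assert all(c["latent_dim"] in (8, 16) for c in result.chosen_params)
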