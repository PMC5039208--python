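"""Group ICA: MDL order, two-stage PCA, Extended Infomax, back-reconstruction."""
import numpy as np
import pytest

from triplenet.gica import (
    GroupICA,
    back_reconstruct,
    estimate_order_mdl,
    extended_infomax,
    match_components,
    two_stage_pca,
)


def _whiten(X):
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / X.shape[1]
    w, U = np.linalg.eigh(cov)
    return (U / np.sqrt(w)).T @ Xc


def _brute_force_mdl(X):
    """Independent re-derivation of the MDL curve for the oracle check."""
    Xc = X - X.mean(axis=1, keepdims=True)
    lam = np.sort(np.linalg.eigvalsh(Xc @ Xc.T / X.shape[1]))[::-1]
    p, n = X.shape
    curve = []
    for k in range(p):
        tail = lam[k:]
        geo = np.exp(np.mean(np.log(tail)))
        arith = np.mean(tail)
        curve.append(-n * (p - k) * np.log(geo / arith)
                     + 0.5 * (k * (2 * p - k) + 1) * np.log(n))
    return np.array(curve)


class TestMdl:
    def test_planted_five_sources(self):
        rng = np.random.default_rng(3)
        S = rng.standard_normal((5, 500)) ** 3
        A = rng.standard_normal((40, 5))
        X = A @ S
        X += rng.standard_normal(X.shape) * (X.std() / np.sqrt(10))  # SNR 10
        k, curve = estimate_order_mdl(X, return_curve=True)
        assert k == 5
        # oracle: brute-force MDL curve has its global argmin at 5
        assert int(np.argmin(_brute_force_mdl(X))) == 5

    def test_white_noise_clamps_to_minimum(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((20, 2000))
        with pytest.warns(RuntimeWarning, match="clamped"):
            k = estimate_order_mdl(X, min_order=2)
        assert k == 2

    def test_fixed_order_override(self):
        # estimation disabled: the configured order is used directly
        ica = GroupICA(n_components=31)
        assert ica.n_components == 31


class TestTwoStagePca:
    def test_single_subject_full_rank_is_lossless(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10, 300))
        white, ops = two_stage_pca([X], order=10)
        # stage-2 output spans the same row space: projecting X onto it
        # reconstructs X
        proj = white @ np.linalg.pinv(white)
        recon = np.linalg.pinv(white) @ white
        np.testing.assert_allclose(X @ recon - X, 0, atol=1e-8)

    def test_rank_k_data_reconstructs_exactly(self):
        # oracle: SVD residual of the rank-k approximation is 0
        rng = np.random.default_rng(1)
        k = 4
        X = rng.standard_normal((30, k)) @ rng.standard_normal((k, 400))
        white, ops = two_stage_pca([X], order=k)
        F = ops["subject_bases"][0]
        residual = X - F @ (F.T @ X)
        assert np.abs(residual).max() < 1e-8

    def test_output_is_white(self):
        rng = np.random.default_rng(2)
        data = [rng.standard_normal((20, 500)) for _ in range(3)]
        white, _ = two_stage_pca(data, order=6)
        cov = white @ white.T / white.shape[1]
        np.testing.assert_allclose(cov, np.eye(6), atol=1e-8)

    def test_order_too_large_raises(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="order"):
            two_stage_pca([rng.standard_normal((5, 50))], order=6)


def _assignment_min_corr(S, truth):
    """Min over true sources of the best |corr|, one-to-one assignment."""
    from scipy.optimize import linear_sum_assignment

    k = truth.shape[0]
    cm = np.corrcoef(np.vstack([S, truth]))[:k, k:]
    r, c = linear_sum_assignment(-np.abs(cm))
    return np.abs(cm)[r, c].min()


class TestExtendedInfomax:
    def test_already_independent_sources_give_near_identity(self):
        rng = np.random.default_rng(5)
        S = rng.standard_normal((3, 5000)) ** 3
        Sc = S - S.mean(1, keepdims=True)
        cov = Sc @ Sc.T / S.shape[1]
        w, U = np.linalg.eigh(cov)
        whitener = (U / np.sqrt(w)).T
        W, _, _ = extended_infomax(whitener @ Sc, random_state=0)
        # total unmixing (W composed with the whitener) ~ signed permutation
        M = np.abs(W @ whitener)
        for row in M:
            row = row / row.max()
            assert np.sort(row)[-2] < 0.1

    @pytest.mark.parametrize("kind", ["super", "mixed"])
    def test_planted_source_recovery(self, kind):
        # oracle: correlation matching against the generated true sources
        rng = np.random.default_rng(6)
        if kind == "super":
            S = rng.standard_normal((3, 10000)) ** 3
        else:
            S = np.vstack([rng.standard_normal((2, 10000)) ** 3,
                           rng.uniform(-1, 1, (1, 10000))])
        S = (S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True)
        A = rng.standard_normal((3, 3))
        white = _whiten(A @ S)
        _, est, _ = extended_infomax(white, random_state=1)
        assert _assignment_min_corr(est, S) > 0.95

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        X = _whiten(rng.standard_normal((3, 3)) @
                    rng.standard_normal((3, 4000)) ** 3)
        W1, S1, _ = extended_infomax(X, random_state=3)
        W2, S2, _ = extended_infomax(X, random_state=3)
        assert np.array_equal(W1, W2)
        assert np.array_equal(S1, S2)

    def test_agrees_with_independent_ica_implementation(self):
        # cross-check: sklearn's FastICA on the same planted mixture must
        # recover sources matching ours component-for-component
        from sklearn.decomposition import FastICA

        rng = np.random.default_rng(21)
        S = rng.standard_normal((3, 8000)) ** 3
        S = (S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True)
        A = rng.standard_normal((3, 3))
        X = A @ S
        white = _whiten(X)
        _, ours, _ = extended_infomax(white, random_state=0)
        theirs = FastICA(n_components=3, random_state=0,
                         whiten="unit-variance").fit_transform(X.T).T
        assert _assignment_min_corr(ours, S) > 0.95
        assert _assignment_min_corr(theirs, S) > 0.95
        cm = np.corrcoef(np.vstack([ours, theirs]))[:3, 3:]
        from scipy.optimize import linear_sum_assignment
        r, c = linear_sum_assignment(-np.abs(cm))
        assert np.abs(cm)[r, c].min() > 0.95

    def test_unmixing_times_data_equals_sources(self):
        rng = np.random.default_rng(8)
        X = _whiten(rng.standard_normal((3, 2000)) ** 3)
        W, S, _ = extended_infomax(X, random_state=0)
        np.testing.assert_allclose(W @ X, S, atol=1e-12)


class TestBackReconstruction:
    def test_single_subject_equals_aggregate(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((4, 4)) @ (rng.standard_normal((4, 2000)) ** 3)
        white, ops = two_stage_pca([X], order=4)
        W, S, _ = extended_infomax(white, random_state=0)
        maps, _ = back_reconstruct(W, ops, 0)
        np.testing.assert_allclose(maps, S, atol=1e-8)

    def test_identical_subjects_get_identical_maps(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((4, 4)) @ (rng.standard_normal((4, 2000)) ** 3)
        white, ops = two_stage_pca([X, X.copy(), X.copy()], order=4)
        W, _, _ = extended_infomax(white, random_state=0)
        maps = [back_reconstruct(W, ops, i)[0] for i in range(3)]
        np.testing.assert_allclose(maps[0], maps[1], atol=1e-6)
        np.testing.assert_allclose(maps[0], maps[2], atol=1e-6)

    def test_unknown_subject_index_raises(self):
        rng = np.random.default_rng(11)
        white, ops = two_stage_pca([rng.standard_normal((4, 500))], order=3)
        W = np.eye(3)
        with pytest.raises(IndexError):
            back_reconstruct(W, ops, 5)

    def test_mean_subject_map_tracks_aggregate(self, tiny_preprocessed):
        subjects, truth = tiny_preprocessed
        ica = GroupICA(n_components=3, random_state=0).fit(subjects)
        mean_maps = np.mean([m for m in ica.subject_maps_], axis=0)
        for c in range(3):
            r = np.corrcoef(mean_maps[c], ica.components_[c])[0, 1]
            assert r > 0.95


class TestMatching:
    def test_identity_templates_match_perfectly(self, tiny_preprocessed):
        subjects, truth = tiny_preprocessed
        ica = GroupICA(n_components=3, random_state=0).fit(subjects)
        mask = subjects[0].mask
        templates = {}
        for i, name in enumerate(("CEN", "DMN", "SN")):
            vol = np.zeros(mask.shape)
            vol[mask] = ica.components_[i]
            templates[name] = vol
        matches = ica.match_components(templates, min_corr=0.2)
        assert sorted(m.component_index for m in matches) == [0, 1, 2]
        for m in matches:
            assert m.spatial_correlation > 0.999

    def test_planted_cohort_recovers_masks(self, tiny_preprocessed):
        from conftest import dice

        subjects, truth = tiny_preprocessed
        ica = GroupICA(n_components=3, random_state=0).fit(subjects)
        matches = ica.match_components(truth.templates, min_corr=0.2)
        mask = subjects[0].mask
        for m in matches:
            vol = np.zeros(mask.shape)
            vol[mask] = ica.components_[m.component_index]
            assert dice(np.abs(vol) > 1.5, truth.masks[m.network]) > 0.5

    def test_orthogonal_template_raises_no_match(self):
        rng = np.random.default_rng(12)
        maps = rng.standard_normal((3, 1000))
        mask = np.ones((1000, 1, 1), dtype=bool)
        template = {"CEN": rng.standard_normal((1000, 1, 1))}
        # random template: |corr| ~ 1/sqrt(1000) << 0.2
        with pytest.raises(ValueError, match="CEN"):
            match_components(maps, template, mask, min_corr=0.2)


def test_sign_convention_max_abs_voxel_positive(tiny_preprocessed):
    subjects, _ = tiny_preprocessed
    ica = GroupICA(n_components=3, random_state=0).fit(subjects)
    for comp in ica.components_:
        assert comp[np.abs(comp).argmax()] > 0
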