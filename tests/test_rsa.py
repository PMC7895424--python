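"""Pattern epoching, whitening, cross-validated RDMs, models, contrasts."""

import numpy as np
import pytest

import seqtag as st
from seqtag.rsa import (
    PatternSet,
    RDM,
    ClassicalMDS,
    contrast_cells,
    crossval_rdm,
    friedman_across_sets,
)


def toy_patterns(n_tokens=3, trials_per_token=10, n_channels=4, spc=5, seed=0,
                 signal=2.0):
    """Noisy patterns with one stable direction per token."""
    rng = np.random.default_rng(seed)
    tokens = [f"t{k}" for k in range(n_tokens)]
    base = rng.standard_normal((n_tokens, n_channels * spc))
    X, labels = [], []
    for k, tok in enumerate(tokens):
        for _ in range(trials_per_token):
            X.append(signal * base[k] + rng.standard_normal(n_channels * spc))
            labels.append(tok)
    return PatternSet(
        X=np.array(X), tokens=labels,
        channel_ids=[f"c{i}" for i in range(n_channels)],
        samples_per_channel=spc,
    )


class TestEpochPatterns:
    def test_vector_length(self, structured_stream, make_pattern_recording):
        rec, ids = make_pattern_recording(structured_stream, "identity", 4, seed=0)
        pats = st.epoch_patterns(rec, structured_stream, ids)
        # one 250-ms SOA at 250 Hz, half-open: floor(0.25 * 250) = 62 samples
        assert pats.samples_per_channel == 62
        assert pats.X.shape[1] == 62 * 4
        assert pats.n_trials == 540

    def test_probes_excluded(self, probed_stream, make_pattern_recording):
        rec, ids = make_pattern_recording(probed_stream, "identity", 4, seed=0)
        pats = st.epoch_patterns(rec, probed_stream, ids)
        assert pats.n_trials == 540  # 556 tokens minus 16 probes

    def test_empty_channel_set_raises(self, structured_stream, make_pattern_recording):
        rec, _ = make_pattern_recording(structured_stream, "identity", 4, seed=0)
        with pytest.raises(ValueError, match="empty"):
            st.epoch_patterns(rec, structured_stream, [])

    def test_bad_window_raises(self, structured_stream, make_pattern_recording):
        rec, ids = make_pattern_recording(structured_stream, "identity", 4, seed=0)
        with pytest.raises(ValueError, match="window"):
            st.epoch_patterns(rec, structured_stream, ids, window_s=(0.2, 0.1))


class TestWhitening:
    def test_residual_covariance_near_identity(self):
        rng = np.random.default_rng(0)
        C = 6
        mix = rng.standard_normal((C, C))
        pats = PatternSet(
            X=(rng.standard_normal((4000, C)) @ mix.T).reshape(4000, C),
            tokens=["a", "b"] * 2000,
            channel_ids=[f"c{i}" for i in range(C)],
            samples_per_channel=1,
        )
        out = st.whiten_and_center(pats)
        cov = np.cov(out.X.T)
        assert np.linalg.norm(cov - np.eye(C)) < 0.25

    def test_identity_covariance_is_centering_only(self):
        pats = toy_patterns(seed=1)
        out = st.whiten_and_center(pats, covariance="identity")
        assert np.allclose(out.X, pats.X - pats.X.mean(axis=0))

    def test_repeated_pattern_centers_to_zero(self):
        X = np.tile(np.arange(8.0), (5, 1))
        w = st.PatternWhitener(covariance="identity").fit(X)
        assert np.allclose(w.transform(X), 0.0)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError, match="2 trials"):
            st.PatternWhitener().fit(np.ones((1, 4)))


class TestCrossvalRDM:
    def test_matches_brute_force_fold_oracle(self):
        pats = toy_patterns(seed=2)
        rdm = crossval_rdm(pats, n_folds=5, seed=3)

        # independent re-implementation of the fold loop
        from sklearn.model_selection import StratifiedKFold

        tokens = np.asarray(pats.tokens)
        ids = pats.token_ids
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=3)
        D = np.zeros((3, 3))
        for tr, va in skf.split(pats.X, tokens):
            for a, ta in enumerate(ids):
                for b, tb in enumerate(ids):
                    m_tr_a = pats.X[tr][tokens[tr] == ta].mean(axis=0)
                    m_va_b = pats.X[va][tokens[va] == tb].mean(axis=0)
                    m_tr_b = pats.X[tr][tokens[tr] == tb].mean(axis=0)
                    m_va_a = pats.X[va][tokens[va] == ta].mean(axis=0)
                    c1 = np.corrcoef(m_tr_a, m_va_b)[0, 1]
                    c2 = np.corrcoef(m_tr_b, m_va_a)[0, 1]
                    D[a, b] += 1 - 0.5 * (c1 + c2)
        D /= 5
        assert np.allclose(rdm.D, D, atol=1e-12)

    def test_identical_patterns_give_zero_distance(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal(20)
        X = np.vstack([base + 0.001 * rng.standard_normal(20) for _ in range(20)])
        pats = PatternSet(X=X, tokens=["a", "b"] * 10,
                          channel_ids=[f"c{i}" for i in range(4)],
                          samples_per_channel=5)
        rdm = crossval_rdm(pats, n_folds=5, seed=0)
        assert abs(rdm.D[0, 1]) < 0.01

    def test_orthogonal_patterns_give_distance_one(self):
        pats = toy_patterns(n_tokens=2, signal=100.0, seed=5)
        rdm = crossval_rdm(pats, n_folds=5, seed=0)
        assert rdm.D[0, 1] == pytest.approx(1.0, abs=0.1)

    def test_symmetry(self):
        rdm = crossval_rdm(toy_patterns(seed=6), n_folds=5, seed=1)
        assert np.allclose(rdm.D, rdm.D.T)

    def test_too_few_occurrences_names_token(self):
        pats = toy_patterns(trials_per_token=3)
        with pytest.raises(ValueError, match="t0"):
            crossval_rdm(pats, n_folds=5)


class TestEmbedding:
    def test_planted_square_recovered(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        rdm = RDM(tokens=list("abcd"), D=D)
        coords, evals = st.embed_2d(rdm)
        D_hat = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(D_hat, D, atol=1e-9)
        assert evals[2] == pytest.approx(0.0, abs=1e-9)

    def test_identical_tokens_coincide(self):
        rdm = RDM(tokens=list("abc"), D=np.zeros((3, 3)))
        coords, _ = st.embed_2d(rdm)
        assert np.allclose(coords, coords[0], atol=1e-12)

    def test_two_tokens_one_dimension(self):
        rdm = RDM(tokens=list("ab"), D=np.array([[0.0, 2.0], [2.0, 0.0]]))
        mds = ClassicalMDS(n_components=2).fit(rdm.D)
        assert mds.eigenvalues_[0] > 1e-9
        assert mds.eigenvalues_[1] == pytest.approx(0.0, abs=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ClassicalMDS().fit(np.array([[0.0, np.nan], [np.nan, 0.0]]))


class TestSchemeModels:
    def test_ordinal_model_blocks(self, inventory):
        m = st.build_scheme_model(inventory, "ordinal")
        M = m.M
        assert M.shape == (12, 12)
        pos = inventory.position_of_token()
        for i, ti in enumerate(m.tokens):
            for j, tj in enumerate(m.tokens):
                if i != j:
                    assert M[i, j] == (0.0 if pos[ti] == pos[tj] else 1.0)
        # three positions x four tokens: 12 off-diagonal zeros per position
        assert (M == 0).sum() == 12 + 3 * 12

    def test_identity_model_masks_same_position(self, visual_inv):
        m = st.build_scheme_model(visual_inv, "identity")
        pos = visual_inv.position_of_token()
        unit = visual_inv.unit_of_token()
        for i, ti in enumerate(m.tokens):
            for j, tj in enumerate(m.tokens):
                if i == j:
                    continue
                if pos[ti] == pos[tj]:
                    assert np.isnan(m.M[i, j])
                else:
                    assert m.M[i, j] == (0.0 if unit[ti] == unit[tj] else 1.0)

    def test_invalid_scheme_raises(self, inventory):
        with pytest.raises(ValueError, match="unknown scheme"):
            st.build_scheme_model(inventory, "syntax")

    def test_model_self_correlation_is_one(self, inventory):
        m = st.build_scheme_model(inventory, "tp")
        rdm = RDM(tokens=m.tokens, D=np.nan_to_num(m.M) + 0.0)
        out = st.model_rdm_comparison(rdm, [m], n_permutations=50, seed=0)
        assert out.loc[0, "rho"] == pytest.approx(1.0)
        assert out.loc[0, "p_perm"] < 0.05

    def test_constant_rdm_rejected(self, inventory):
        m = st.build_scheme_model(inventory, "tp")
        rdm = RDM(tokens=m.tokens, D=np.ones((12, 12)))
        with pytest.raises(ValueError, match="constant"):
            st.model_rdm_comparison(rdm, [m])


class TestContrastCells:
    def test_tp_cells_for_triplets(self, inventory):
        within, between = contrast_cells(inventory, "tp")
        pos = inventory.position_of_token()
        toks = list(inventory.token_alphabet)
        assert len(within) == 6  # C(4,2) first-position pairs
        # second-second (6) + second-third (16); third-third excluded
        assert len(between) == 22
        for i, j in within:
            assert pos[toks[i]] == pos[toks[j]] == 1
        with_tt = contrast_cells(inventory, "tp", include_third_third=True)[1]
        assert len(with_tt) == 28

    def test_identity_cells_exclude_same_position(self, inventory):
        within, between = contrast_cells(inventory, "identity")
        pos = inventory.position_of_token()
        toks = list(inventory.token_alphabet)
        assert len(within) == 12  # 4 units x 3 cross-position pairs
        assert len(between) == 36
        for i, j in within + between:
            assert pos[toks[i]] != pos[toks[j]]

    def test_pair_inventory_tp_cells(self, visual_inv):
        within, between = contrast_cells(visual_inv, "tp")
        assert len(within) == 6 and len(between) == 6


class TestResampledContrast:
    def test_matching_scheme_detected(self, structured_stream, make_pattern_recording):
        rec, ids = make_pattern_recording(structured_stream, "identity", 12, seed=8)
        pats = st.whiten_and_center(st.epoch_patterns(rec, structured_stream, ids))
        c = st.resampled_contrast(pats, "identity", n_resamples=50, seed=0)
        assert np.mean(c.diff) > 0
        assert c.p_value < 0.01
        # mismatched contrast is not positively significant
        c_tp = st.resampled_contrast(pats, "tp", n_resamples=50, seed=0)
        assert not (np.mean(c_tp.diff) > 0 and c_tp.p_value < 0.05)

    def test_single_resample_rejected(self, structured_stream, make_pattern_recording):
        rec, ids = make_pattern_recording(structured_stream, "identity", 4, seed=0)
        pats = st.epoch_patterns(rec, structured_stream, ids)
        with pytest.raises(ValueError, match="n_resamples"):
            st.resampled_contrast(pats, "tp", n_resamples=1)

    def test_two_channels_required(self, structured_stream, make_pattern_recording):
        rec, ids = make_pattern_recording(structured_stream, "identity", 4, seed=0)
        pats = st.epoch_patterns(rec, structured_stream, ["c0"])
        with pytest.raises(ValueError, match="2 channels"):
            st.resampled_contrast(pats, "tp", n_resamples=10)

    def test_seed_reproducibility(self, structured_stream, make_pattern_recording):
        rec, ids = make_pattern_recording(structured_stream, "tp", 6, seed=1)
        pats = st.epoch_patterns(rec, structured_stream, ids)
        c1 = st.resampled_contrast(pats, "tp", n_resamples=20, seed=5)
        c2 = st.resampled_contrast(pats, "tp", n_resamples=20, seed=5)
        assert np.array_equal(c1.within_z, c2.within_z)


class TestFriedman:
    def _contrast(self, diff_mean, n=50, seed=0, label="s"):
        rng = np.random.default_rng(seed)
        w = rng.normal(diff_mean, 0.1, n)
        b = np.zeros(n)
        return st.ContrastResult(
            scheme="tp", electrode_set=label, within_z=w, between_z=b,
            within_cell_z=np.zeros(3), between_cell_z=np.zeros(3),
            statistic=0.0, p_value=1.0,
        )

    def test_shifted_set_detected(self):
        sets = [self._contrast(0.0, seed=1, label="a"),
                self._contrast(0.0, seed=2, label="b"),
                self._contrast(1.0, seed=3, label="c")]
        out = friedman_across_sets(sets)
        assert out["test"] == "friedman"
        assert out["p_value"] < 0.001
        flagged = {p["set_a"] for p in out["pairwise"] if p["p_bonferroni"] < 0.05}
        flagged |= {p["set_b"] for p in out["pairwise"] if p["p_bonferroni"] < 0.05}
        assert "c" in flagged

    def test_two_sets_fall_back_to_ranksum(self):
        out = friedman_across_sets([self._contrast(0.0, seed=1),
                                    self._contrast(0.5, seed=2)])
        assert out["test"] == "ranksum"
        assert "Friedman" in out["note"]

    def test_mismatched_resample_counts_rejected(self):
        with pytest.raises(ValueError, match="resample count"):
            friedman_across_sets([self._contrast(0, n=50), self._contrast(0, n=40),
                                  self._contrast(0, n=50)])
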