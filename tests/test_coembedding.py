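import numpy as np
import pytest

from moable.coembedding import (
    CoembeddingModel,
    EncoderSpec,
    TrainConfig,
    batch_triplet_loss,
    cosine_similarity,
    embed_gp_signatures,
    EmbeddingBank,
    train,
    triplet_loss,
    _triplet_batch_loss_and_grads,
)
from moable.errors import DimensionError, ValidationError, ZeroVectorError
from moable.pipeline import build_train_pairs
from moable.io_formats import SplitSpec, split_compounds


class TestCosineSimilarity:
    @pytest.mark.parametrize("u,v,expected", [
        ([1, 0], [1, 0], 1.0),
        ([1, 0], [0, 1], 0.0),
        ([1, 2], [2, 4], 1.0),  # scale invariance
    ])
    def test_examples(self, u, v, expected):
        assert cosine_similarity(u, v) == pytest.approx(expected)

    def test_zero_vector_raises(self):
        with pytest.raises(ZeroVectorError):
            cosine_similarity([0, 0], [1, 0])

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            cosine_similarity([1, 0], [1, 0, 0])


class TestTripletLoss:
    @pytest.mark.parametrize("sp,sn,a,expected", [
        (0.9, 0.1, 0.2, 0.0),
        (0.5, 0.5, 0.2, 0.2),
        (-0.2, 0.4, 0.1, 0.7),
    ])
    def test_hinge_examples(self, sp, sn, a, expected):
        assert triplet_loss(sp, sn, a) == pytest.approx(expected)

    def test_nonnegative_and_monotone_on_grid(self):
        grid = np.linspace(-1, 1, 41)
        vals = np.array([[triplet_loss(sp, sn, 0.3) for sn in grid] for sp in grid])
        assert (vals >= 0).all()
        # non-increasing in sim_pos (rows), non-decreasing in sim_neg (cols)
        assert (np.diff(vals, axis=0) <= 1e-12).all()
        assert (np.diff(vals, axis=1) >= -1e-12).all()

    def test_batch_equals_mean_of_singles(self, rng):
        sp = rng.uniform(-1, 1, 100)
        sn = rng.uniform(-1, 1, 100)
        batched = batch_triplet_loss(sp, sn, 0.2)
        singles = np.mean([triplet_loss(a, b, 0.2) for a, b in zip(sp, sn)])
        assert batched == pytest.approx(singles, abs=1e-12)


class TestEncoders:
    @pytest.fixture
    def model(self):
        return CoembeddingModel(EncoderSpec(32, [16], 8),
                                EncoderSpec(20, [16], 8), seed=0)

    def test_output_dimensions(self, model, rng):
        out = model.forward_structure(rng.integers(0, 2, (1, 32)))
        assert out.shape == (1, 8)
        out = model.forward_signature(rng.standard_normal((4, 20)))
        assert out.shape == (4, 8)

    def test_batching_consistency(self, model, rng):
        X = rng.integers(0, 2, (5, 32)).astype(float)
        batch = model.forward_structure(X)
        singles = np.vstack([model.forward_structure(X[i:i + 1]) for i in range(5)])
        np.testing.assert_allclose(batch, singles, atol=1e-12)

    def test_dimension_mismatch_is_shape_error(self, model, rng):
        with pytest.raises(DimensionError, match="32"):
            model.forward_structure(rng.integers(0, 2, (1, 100)))

    def test_empty_batch(self, model):
        assert model.forward_signature(np.empty((0, 20))).shape == (0, 8)

    def test_mismatched_output_dims_rejected(self):
        with pytest.raises(ValidationError):
            CoembeddingModel(EncoderSpec(8, [4], 2), EncoderSpec(8, [4], 3))

    def test_gradient_matches_finite_differences(self, rng):
        """Backprop through both encoders and the cosine hinge is exact."""
        m = CoembeddingModel(EncoderSpec(6, [5], 4), EncoderSpec(7, [5], 4), seed=1)
        Xs = rng.standard_normal((3, 7))
        Xp = rng.standard_normal((3, 6))
        Xn = rng.standard_normal((3, 6))
        _, g_sig, g_str = _triplet_batch_loss_and_grads(m, Xs, Xp, Xn, 0.5)
        params = m.f_sig.params() + m.f_str.params()
        grads = g_sig + g_str
        eps = 1e-6
        for p, g in zip(params, grads):
            flat = p.reshape(-1)
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                l1, *_ = _triplet_batch_loss_and_grads(m, Xs, Xp, Xn, 0.5)
                flat[idx] = orig - eps
                l2, *_ = _triplet_batch_loss_and_grads(m, Xs, Xp, Xn, 0.5)
                flat[idx] = orig
                assert g.reshape(-1)[idx] == pytest.approx(
                    (l1 - l2) / (2 * eps), abs=1e-6
                )


@pytest.fixture(scope="module")
def trained(request):
    corpus = request.getfixturevalue("tiny_corpus")
    cfg = request.getfixturevalue("tiny_train_config")
    train_recs, val_recs, _ = split_compounds(corpus.compounds, SplitSpec(seed=3))
    pairs = build_train_pairs(train_recs, corpus.compound_signatures)
    val_pairs = build_train_pairs(val_recs, corpus.compound_signatures)
    model, log = train(pairs, cfg, validation_pairs=val_pairs)
    return corpus, cfg, pairs, val_pairs, model, log


class TestTraining:
    def test_validation_loss_decreases(self, trained):
        *_, log = trained
        assert log[-1]["val_loss"] < log[0]["val_loss"]

    def test_training_is_deterministic(self, trained):
        corpus, cfg, pairs, val_pairs, model, _ = trained
        model2, _ = train(pairs, cfg, validation_pairs=val_pairs)
        for a, b in zip(model.f_str.params(), model2.f_str.params()):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(model.f_sig.params(), model2.f_sig.params())\
                :
            np.testing.assert_array_equal(a, b)

    def test_structure_queries_retrieve_own_signatures(self, trained):
        """Cross-modal retrieval: querying all signature embeddings with a
        compound's structure embedding ranks its own signatures near the top."""
        from moable.coembedding import cosine_similarity_matrix
        corpus, _, _, _, model, _ = trained
        sm = corpus.compound_signatures
        Zsig = model.forward_signature(sm.values.T)
        owner = np.array([sm.column_meta[s]["perturbagen_id"] for s in sm.sample_ids])
        fps = {c.compound_id: c.fingerprint for c in corpus.compounds}
        ids = list(fps)
        Zstr = model.forward_structure(np.stack([fps[c].astype(float) for c in ids]))
        S = cosine_similarity_matrix(Zstr, Zsig)
        ranks = []
        for i, cid in enumerate(ids):
            order = np.argsort(-S[i])
            ranks.append(np.where(owner[order] == cid)[0].min() / len(owner))
        assert np.median(ranks) <= 0.10

    def test_noiseless_corpus_separates_pairs_by_margin(self, tiny_train_config):
        """When signatures are deterministic functions of fingerprints, the
        trained model separates matched from mismatched pairs by at least the
        training margin on average."""
        from moable.coembedding import cosine_similarity_matrix
        from moable.synthetic_data import SimConfig, simulate
        corpus = simulate(SimConfig(
            n_compounds=40, n_genes=10, n_pathways=2, genes_per_pathway=5,
            n_bits=256, sig_dim=64, replicates_per_gene=2,
            signatures_per_compound=2, motif_bits_per_target=16,
            decoy_compound_fraction=0.0, structure_noise_rate=0.0,
            signature_noise_sd=0.0, seed=77))
        pairs = build_train_pairs(corpus.compounds, corpus.compound_signatures)
        cfg = tiny_train_config
        model, _ = train(pairs, cfg, validation_pairs=pairs)
        Xs = np.stack([p.signature for p in pairs])
        Xp = np.stack([p.fingerprint.astype(float) for p in pairs])
        cids = np.array([p.compound_id for p in pairs])
        Zs, Zp = model.forward_signature(Xs), model.forward_structure(Xp)
        S = cosine_similarity_matrix(Zs, Zp)
        same = cids[:, None] == cids[None, :]
        # compounds sharing a target gene are bitwise identical in the
        # noiseless limit, so only distinct-target pairs are real negatives
        targets = np.array([corpus.target_map[c] for c in cids])
        diff_target = targets[:, None] != targets[None, :]
        assert S[same].mean() - S[diff_target].mean() >= cfg.margin_alpha

    def test_single_compound_is_rejected(self, rng):
        from moable.coembedding import TrainPair
        pairs = [TrainPair("only", rng.integers(0, 2, 16).astype(np.uint8),
                           rng.standard_normal(8)) for _ in range(4)]
        with pytest.raises(ValidationError):
            train(pairs, TrainConfig(batch_size=2, max_epochs=1))


class TestArchiveAndBank:
    def test_archive_round_trip_identical_embeddings(self, trained, tmp_path):
        corpus, *_, model, _ = trained
        model.save(tmp_path / "model")
        back = CoembeddingModel.load(tmp_path / "model")
        X = corpus.compound_signatures.values[:, :5].T
        np.testing.assert_array_equal(model.forward_signature(X),
                                      back.forward_signature(X))

    def test_gp_bank_contents_and_definitional_equality(self, trained):
        corpus, *_, model, _ = trained
        bank = embed_gp_signatures(model, corpus.gp_signatures)
        gp_cols = corpus.gp_signatures.gp_columns()
        assert len(bank) == len(gp_cols)
        assert set(bank.provenance) == {"gp_signature"}
        sid = gp_cols[0]
        direct = model.forward_signature(
            corpus.gp_signatures.column(sid)[None, :]
        )[0]
        np.testing.assert_allclose(bank.get(sid), direct, atol=1e-12)

    def test_bank_tsv_round_trip(self, trained, tmp_path):
        corpus, *_, model, _ = trained
        bank = embed_gp_signatures(model, corpus.gp_signatures)
        path = tmp_path / "bank.tsv"
        bank.save_tsv(path)
        back = EmbeddingBank.load_tsv(path)
        assert back.ids == bank.ids
        assert back.meta == bank.meta
        np.testing.assert_allclose(back.vectors, bank.vectors, rtol=1e-9)

    def test_gp_entries_require_target_gene(self):
        with pytest.raises(ValidationError):
            EmbeddingBank(["a"], np.ones((1, 3)), ["gp_signature"], [{}])
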