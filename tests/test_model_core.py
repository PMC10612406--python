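import numpy as np
import pytest

from kmerlm.kmer_tokens import build_vocabulary, mask_contiguous, tokenize
from kmerlm.model_core import (
    CheckpointError, ConfigValidationError, ModelConfig, ModelState,
    build_model, count_parameters, count_parameters_by_walk,
    extract_token_embeddings, forward_hidden, load_model, mlm_loss,
    mlm_loss_batch, param_group, reinitialize_module, save_model,
)


def full_scale_config():
    return ModelConfig(k=5, hidden=768, layers=12, heads=12, ffn=3072,
                       max_positions=512, type_vocab=2)


class TestConfig:
    def test_vocab_size_derived(self):
        assert ModelConfig(k=5).vocab_size == 1029

    def test_divisibility_error(self):
        with pytest.raises(ConfigValidationError, match="divisible"):
            ModelConfig(hidden=65, heads=4)

    def test_error_lists_all_violations(self):
        with pytest.raises(ConfigValidationError) as err:
            ModelConfig(hidden=65, heads=4, dropout=2.0)
        assert "divisible" in str(err.value) and "dropout" in str(err.value)


class TestParameterCount:
    def test_full_scale_encoding_params(self):
        pc = count_parameters(full_scale_config())
        assert pc.encoding_params == 85_054_464

    def test_full_scale_fraction(self):
        pc = count_parameters(full_scale_config())
        assert round(100 * pc.fraction_encoding, 1) == 98.6

    def test_closed_form_equals_walk_mini(self, mini_model):
        closed = count_parameters(mini_model.config)
        walk = count_parameters_by_walk(mini_model)
        assert (closed.embedding_params, closed.encoding_params,
                closed.head_params) == \
            (walk.embedding_params, walk.encoding_params,
             walk.head_params)

    def test_closed_form_equals_walk_random_configs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            heads = int(rng.choice([1, 2, 4]))
            cfg = ModelConfig(
                k=int(rng.integers(1, 5)),
                hidden=heads * int(rng.integers(2, 9)),
                layers=int(rng.integers(1, 4)),
                heads=heads,
                ffn=int(rng.integers(4, 65)),
                max_positions=int(rng.integers(16, 65)),
                type_vocab=int(rng.integers(1, 3)),
                tie_weights=bool(rng.integers(0, 2)))
            closed = count_parameters(cfg)
            walk = count_parameters_by_walk(build_model(cfg))
            assert (closed.embedding_params, closed.encoding_params,
                    closed.head_params) == \
                (walk.embedding_params, walk.encoding_params,
                 walk.head_params)

    def test_partition_total_disjoint(self, mini_model):
        groups = {param_group(name) for name in mini_model.params}
        assert groups == {"embedding", "encoding", "head"}


class TestBuildModel:
    def test_forward_pass_runs(self, mini_model, vocab3):
        ts = tokenize("ACGTACGTACGTACGT", vocab3)
        hidden, _ = forward_hidden(mini_model, np.array([ts.ids]))
        assert hidden.shape == (1, len(ts.ids), 32)
        assert np.all(np.isfinite(hidden))

    def test_same_seed_identical(self):
        cfg = ModelConfig(k=2, hidden=16, layers=1, heads=2, ffn=32,
                          max_positions=32, seed=5)
        a, b = build_model(cfg), build_model(cfg)
        for name in a.params:
            np.testing.assert_array_equal(a.params[name], b.params[name])

    def test_different_seed_differs(self):
        base = dict(k=2, hidden=16, layers=1, heads=2, ffn=32,
                    max_positions=32)
        a = build_model(ModelConfig(seed=1, **base))
        b = build_model(ModelConfig(seed=2, **base))
        assert not np.array_equal(a.params["embedding.token"],
                                  b.params["embedding.token"])


class TestReinitialize:
    def test_encoding_scope_keeps_embeddings(self, mini_model):
        out = reinitialize_module(mini_model, "encoding", seed=99)
        np.testing.assert_array_equal(out.params["embedding.token"],
                                      mini_model.params["embedding.token"])
        assert not np.array_equal(out.params["encoding.0.attn.wq"],
                                  mini_model.params["encoding.0.attn.wq"])

    def test_encoding_scope_embedding_table_identical(self, mini_model):
        before = extract_token_embeddings(mini_model)
        out = reinitialize_module(mini_model, "encoding", seed=99)
        after = extract_token_embeddings(out)
        np.testing.assert_array_equal(before.matrix, after.matrix)

    def test_embedding_scope_keeps_encoder(self, mini_model):
        out = reinitialize_module(mini_model, "embedding", seed=99)
        np.testing.assert_array_equal(out.params["encoding.1.ffn.w1"],
                                      mini_model.params["encoding.1.ffn.w1"])
        assert not np.array_equal(out.params["embedding.token"],
                                  mini_model.params["embedding.token"])

    def test_all_scope_reproduces_build(self, mini_model):
        out = reinitialize_module(mini_model, "all", seed=123)
        cfg = ModelConfig(**{**mini_model.config.__dict__, "seed": 123})
        fresh = build_model(cfg)
        for name in out.params:
            np.testing.assert_array_equal(out.params[name],
                                          fresh.params[name])

    def test_all_scope_changes_every_group(self, mini_model):
        out = reinitialize_module(mini_model, "all", seed=321)
        for name in ("embedding.token", "encoding.0.attn.wq", "head.w"):
            assert not np.array_equal(out.params[name],
                                      mini_model.params[name])

    def test_unknown_scope(self, mini_model):
        with pytest.raises(ValueError, match="scope"):
            reinitialize_module(mini_model, "attention", seed=0)

    def test_input_not_mutated(self, mini_model):
        snapshot = mini_model.params["encoding.0.attn.wq"].copy()
        reinitialize_module(mini_model, "all", seed=7)
        np.testing.assert_array_equal(
            mini_model.params["encoding.0.attn.wq"], snapshot)


class TestExtractEmbeddings:
    def test_5mer_row_counts(self):
        m = build_model(ModelConfig(k=5, hidden=16, layers=1, heads=2,
                                    ffn=32, max_positions=32))
        assert extract_token_embeddings(m, True).n_rows == 1029
        assert extract_token_embeddings(m, False).n_rows == 1024

    def test_row_matches_weight(self, mini_model, vocab3):
        table = extract_token_embeddings(mini_model)
        i = vocab3.index["AAA"]
        np.testing.assert_array_equal(
            table.vector("AAA"),
            mini_model.params["embedding.token"][i])


class TestMlmLoss:
    def test_untrained_near_uniform(self):
        m = build_model(ModelConfig(k=5, hidden=32, layers=1, heads=2,
                                    ffn=64, max_positions=64, seed=0))
        v = build_vocabulary(5)
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        ts = tokenize(seq, v)
        plan = mask_contiguous(ts, 0.2, rng_seed=0)
        loss, preds = mlm_loss(m, ts, plan)
        assert loss == pytest.approx(np.log(1029), abs=0.3)
        assert len(preds) == len(plan.masked_positions)

    def test_biased_head_drives_loss_to_zero(self, mini_model, vocab3):
        m = mini_model.copy()
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 20))
        ts = tokenize(seq, vocab3)
        plan = mask_contiguous(ts, 0.2, rng_seed=0,
                               replace_probs=(1, 0, 0))
        # bias the output head fully toward one true token's id
        true_id = ts.ids[plan.masked_positions[0]]
        m.params["head.b"] = np.zeros(vocab3.size)
        m.params["head.b"][true_id] = 1e4
        m.params["head.w"] = np.zeros_like(m.params["head.w"])
        single = type(plan)(runs=[(plan.masked_positions[0], 1)],
                            actions={plan.masked_positions[0]:
                                     "mask-token"},
                            target_rate=0.1, achieved_rate=0.1, seed=0)
        loss, preds = mlm_loss(m, ts, single)
        assert loss < 1e-6
        assert preds[0] == true_id

    def test_loss_ignores_unmasked_labels(self, mini_model, vocab3):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
        ts = tokenize(seq, vocab3)
        plan = mask_contiguous(ts, 0.15, rng_seed=1,
                               replace_probs=(1, 0, 0))
        ids = np.array([ts.ids])
        from kmerlm.kmer_tokens import apply_mask
        masked_input = np.array([apply_mask(ts, plan)])
        mask = np.zeros_like(ids, dtype=bool)
        mask[0, plan.masked_positions] = True
        loss1, _ = mlm_loss_batch(mini_model, masked_input, ids, mask)
        scrambled = ids.copy()
        unmasked = ~mask
        scrambled[unmasked] = (scrambled[unmasked] + 7) % 69
        loss2, _ = mlm_loss_batch(mini_model, masked_input, scrambled,
                                  mask)
        assert loss1 == loss2

    def test_zero_masked_positions_error(self, mini_model, vocab3):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 20))
        ts = tokenize(seq, vocab3)
        empty = type(mask_contiguous(ts, 0.2, 0))(
            runs=[], actions={}, target_rate=0.1, achieved_rate=0,
            seed=0)
        with pytest.raises(ValueError, match="zero masked"):
            mlm_loss(mini_model, ts, empty)


class TestGradients:
    def test_finite_difference_check(self):
        cfg = ModelConfig(k=1, hidden=8, layers=2, heads=2, ffn=16,
                          max_positions=16, seed=3)
        state = build_model(cfg)
        rng = np.random.default_rng(0)
        B, T = 2, 7
        input_ids = rng.integers(0, cfg.vocab_size, size=(B, T))
        labels = rng.integers(5, cfg.vocab_size, size=(B, T))
        mask = rng.random((B, T)) < 0.4
        mask[0, 0] = True

        _, _, grads = mlm_loss_batch(state, input_ids, labels, mask,
                                     with_grads=True)
        eps = 1e-6
        for name, g in grads.items():
            p = state.params[name]
            for _ in range(4):
                idx = tuple(int(rng.integers(0, s)) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = mlm_loss_batch(state, input_ids, labels, mask)
                p[idx] = orig - eps
                lm, _ = mlm_loss_batch(state, input_ids, labels, mask)
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-7), \
                    f"gradient mismatch for {name}{idx}"

    def test_permutation_equivariance(self):
        # permuting vocabulary ids consistently in inputs, token
        # embeddings and head rows permutes nothing observable
        cfg = ModelConfig(k=1, hidden=8, layers=1, heads=2, ffn=16,
                          max_positions=16, seed=0)
        state = build_model(cfg)
        rng = np.random.default_rng(1)
        ids = rng.integers(0, 9, size=(1, 6))
        hidden, _ = forward_hidden(state, ids)
        logits = hidden @ state.params["head.w"].T + state.params["head.b"]

        perm = rng.permutation(9)
        inv = np.argsort(perm)
        permuted = state.copy()
        permuted.params["embedding.token"] = \
            state.params["embedding.token"][inv]
        permuted.params["head.w"] = state.params["head.w"][inv]
        permuted.params["head.b"] = state.params["head.b"][inv]
        hidden2, _ = forward_hidden(permuted, perm[ids])
        logits2 = hidden2 @ permuted.params["head.w"].T \
            + permuted.params["head.b"]
        np.testing.assert_allclose(logits2[..., perm], logits, atol=1e-10)


class TestSerialization:
    def test_round_trip(self, mini_model, tmp_path):
        path = tmp_path / "model.npz"
        save_model(mini_model, path)
        loaded = load_model(path)
        assert loaded.config == mini_model.config
        for name in mini_model.params:
            np.testing.assert_array_equal(loaded.params[name],
                                          mini_model.params[name])

    def test_config_echo_preserved(self, mini_model, tmp_path):
        path = tmp_path / "model.npz"
        save_model(mini_model, path)
        assert load_model(path).provenance == mini_model.provenance

    def test_shape_mismatch_rejected(self, mini_model, tmp_path):
        path = tmp_path / "model.npz"
        save_model(mini_model, path)
        import json
        import numpy as np
        data = dict(np.load(path))
        meta = json.loads(bytes(data["__meta__"]).decode())
        meta["config"]["k"] = 2  # wrong k for the stored shapes
        meta["config"]["vocab_size"] = None
        data["__meta__"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **data)
        with pytest.raises(CheckpointError):
            load_model(path)
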