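import numpy as np
import pytest

from morphgen.autodiff import Tensor
from morphgen.phantoms import CovariateRecord
from morphgen.seq_model import (
    ConditioningSet,
    CovariateStats,
    SeqModelConfig,
    TokenTransformer,
    conditioning_from_record,
    derasterize,
    next_token_logits,
    rasterize,
    sample_sequence,
)
from morphgen.seq_model.model import sequence_nll

rng = np.random.default_rng(5)


@pytest.fixture(scope="module")
def records():
    return [
        CovariateRecord(sex=i % 2, age=45.0 + 3 * i, ventricle_volume=200.0 + 60 * i,
                        brain_size=0.95 + 0.01 * i)
        for i in range(6)
    ]


@pytest.fixture(scope="module")
def stats(records):
    return CovariateStats.from_records(records)


@pytest.fixture(scope="module")
def tiny_model(stats):
    cfg = SeqModelConfig.desk(layers=2, width=32, heads=2, num_tokens=16)
    return TokenTransformer(cfg, stats, np.random.default_rng(0))


class TestRaster:
    def test_definition_2x2x2(self):
        grid = np.arange(8).reshape(2, 2, 2)
        np.testing.assert_array_equal(rasterize(grid), np.arange(8))

    def test_roundtrip_identity(self):
        grid = rng.integers(0, 50, size=(3, 4, 5))
        np.testing.assert_array_equal(derasterize(rasterize(grid), (3, 4, 5)), grid)

    def test_full_scale_grid_length(self):
        grid = np.zeros((10, 14, 10), dtype=int)
        assert rasterize(grid).size == 1400

    def test_dims_mismatch(self):
        with pytest.raises(ValueError):
            derasterize(np.zeros(7, dtype=int), (2, 2, 2))


class TestConditioning:
    def test_missing_covariate_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            ConditioningSet(values={"sex": 0})

    def test_unknown_categorical_level_raises(self, tiny_model, records):
        cs = conditioning_from_record(records[0])
        cs.values["pathology"] = "mystery"
        with pytest.raises(ValueError, match="unknown level"):
            tiny_model.cond_embedder([cs])

    def test_order_from_schema_not_record(self, tiny_model, records):
        cs = conditioning_from_record(records[0])
        shuffled = ConditioningSet(
            values=dict(reversed(list(cs.values.items()))),
            aug_params=cs.aug_params)
        a = tiny_model.cond_embedder([cs]).data
        b = tiny_model.cond_embedder([shuffled]).data
        np.testing.assert_array_equal(a, b)

    def test_tokens_linear_in_continuous_covariate(self, tiny_model, records):
        # token for a continuous covariate is affine in its standardized value
        emb = tiny_model.cond_embedder
        def tok(v):
            cs = conditioning_from_record(records[0].replace(ventricle_volume=v))
            return emb([cs]).data[0, 2]  # schema slot 2 = ventricle_volume
        t0, t1, t2 = tok(200.0), tok(300.0), tok(400.0)
        np.testing.assert_allclose(t2 - t1, t1 - t0, rtol=1e-8)

    def test_zero_standardized_value_gives_bias(self, tiny_model, stats, records):
        emb = tiny_model.cond_embedder
        mean_age = stats.means["age"]
        cs = conditioning_from_record(records[0].replace(age=mean_age))
        got = emb([cs]).data[0, 1]
        np.testing.assert_allclose(got, emb.cont_age.bias.data, atol=1e-12)


class TestNextTokenLogits:
    def test_causality_bit_identical_prefix(self, tiny_model, records):
        cfg = tiny_model.cfg
        cs = conditioning_from_record(records[0])
        seq = np.concatenate([[cfg.bos], rng.integers(0, cfg.num_tokens, 7)])
        l1 = next_token_logits(seq, cs, tiny_model)
        seq2 = seq.copy()
        seq2[5:] = (seq2[5:] + 1) % cfg.num_tokens
        l2 = next_token_logits(seq2, cs, tiny_model)
        np.testing.assert_array_equal(l1[:5], l2[:5])

    def test_softmax_rows_normalized(self, tiny_model, records):
        cfg = tiny_model.cfg
        seq = np.concatenate([[cfg.bos], rng.integers(0, cfg.num_tokens, 7)])
        logits = next_token_logits(seq, conditioning_from_record(records[0]), tiny_model)
        p = np.exp(logits - logits.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)

    def test_requires_bos(self, tiny_model, records):
        with pytest.raises(ValueError, match="bos"):
            next_token_logits(np.zeros(4, dtype=int),
                              conditioning_from_record(records[0]), tiny_model)

    def test_rejects_out_of_range_token(self, tiny_model, records):
        cfg = tiny_model.cfg
        seq = np.array([cfg.bos, cfg.num_tokens + 3])
        with pytest.raises(ValueError, match="out of range"):
            next_token_logits(seq, conditioning_from_record(records[0]), tiny_model)

    def test_conditioning_reaches_logits(self, tiny_model, records):
        cfg = tiny_model.cfg
        seq = np.concatenate([[cfg.bos], rng.integers(0, cfg.num_tokens, 7)])
        l1 = next_token_logits(seq, conditioning_from_record(records[0]), tiny_model)
        l2 = next_token_logits(seq, conditioning_from_record(records[5]), tiny_model)
        assert not np.allclose(l1, l2)

    def test_handcrafted_single_layer_oracle(self, stats, records):
        """1-layer, 1-head model with surgically set weights reproduces a
        by-hand pass through the attention formula."""
        cfg = SeqModelConfig.desk(layers=1, width=4, heads=1, num_tokens=4,
                                  cross_attention_parity=1)  # layer 0 = self-attn
        model = TokenTransformer(cfg, stats, np.random.default_rng(0))
        block = model.blocks[0]
        # neutralize everything except raw attention
        for norm in (block.attn.norm, model.final_norm):
            norm.gain.data[:] = 1.0
        for lin, mat in (
            (block.attn.wq, np.eye(4)),
            (block.attn.wk, np.eye(4)),
            (block.attn.wv, np.eye(4)),
            (block.attn.wo, np.eye(4)),
        ):
            lin.weight.data = mat.astype(float)
            lin.bias.data[:] = 0.0
        for t in (block.attn.bias.table_x, block.attn.bias.table_y,
                  block.attn.bias.table_z):
            t.data[:] = 1.0  # product -> constant bias 1
        block.attn.gate.proj.weight.data[:] = 0.0
        block.attn.gate.proj.bias.data[:] = 1e4  # plain residual
        block.ff.up.weight.data[:] = 0.0
        block.ff.up.bias.data[:] = 0.0
        block.ff.down.weight.data[:] = 0.0
        block.ff.down.bias.data[:] = 0.0
        model.head.weight.data = np.eye(4).astype(float)
        model.head.bias.data[:] = 0.0

        seq = np.array([cfg.bos, 1, 2])
        cs = conditioning_from_record(records[0])
        got = next_token_logits(seq, cs, model)

        # hand computation
        E = model.embed.weight.data
        x = E[[cfg.bos, 1, 2]]
        h = x / np.sqrt((x**2).mean(axis=1, keepdims=True) + 1e-8)
        logits = h @ h.T / 2.0 + 1.0  # d_k = 4, constant bias 1
        out = np.zeros_like(x)
        for j in range(3):
            l_row = logits[j, : j + 1]
            p = np.exp(l_row - l_row.max())
            p /= p.sum()
            out[j] = x[j] + p @ h[: j + 1]  # residual + attention
        final = out / np.sqrt((out**2).mean(axis=1, keepdims=True) + 1e-8)
        np.testing.assert_allclose(got, final, atol=1e-6)


class TestSequenceNLL:
    def test_uniform_logits_give_log_m(self, stats, records):
        cfg = SeqModelConfig.desk(layers=1, width=32, heads=2, num_tokens=16)
        model = TokenTransformer(cfg, stats, np.random.default_rng(0))
        model.head.weight.data[:] = 0.0
        model.head.bias.data[:] = 0.0
        seqs = rng.integers(0, 16, size=(2, cfg.sequence_length))
        csets = [conditioning_from_record(records[0])] * 2
        nll = sequence_nll(seqs, csets, model)
        assert np.isclose(nll.item(), np.log(16))

    def test_perfect_model_zero_nll(self, stats, records):
        cfg = SeqModelConfig.desk(layers=1, width=32, heads=2, num_tokens=4)
        model = TokenTransformer(cfg, stats, np.random.default_rng(0))
        seqs = np.full((1, cfg.sequence_length), 2)
        # saturate the head towards class 2
        model.head.weight.data[:] = 0.0
        model.head.bias.data[:] = 0.0
        model.head.bias.data[2] = 1e4
        csets = [conditioning_from_record(records[0])]
        assert sequence_nll(seqs, csets, model).item() < 1e-8

    def test_matches_cross_entropy_oracle(self, tiny_model, records):
        cfg = tiny_model.cfg
        seqs = rng.integers(0, cfg.num_tokens, size=(2, cfg.sequence_length))
        csets = [conditioning_from_record(records[i]) for i in range(2)]
        nll = sequence_nll(seqs, csets, tiny_model).item()
        total = 0.0
        for b in range(2):
            inp = np.concatenate([[cfg.bos], seqs[b, :-1]])
            logits = next_token_logits(inp, csets[b], tiny_model)
            for j in range(cfg.sequence_length):
                row = logits[j]
                lse = np.log(np.exp(row - row.max()).sum()) + row.max()
                total += -(row[seqs[b, j]] - lse)
        np.testing.assert_allclose(nll, total / seqs.size, rtol=1e-9)

    def test_causality_gradient_zero_from_future(self, tiny_model, records):
        """Gradient of position-k loss w.r.t. embeddings of tokens > k is 0."""
        cfg = tiny_model.cfg
        seqs = rng.integers(0, cfg.num_tokens, size=(1, cfg.sequence_length))
        cs = [conditioning_from_record(records[0])]
        inp = np.concatenate([[cfg.bos], seqs[0, :-1]])[None, :]
        logits = tiny_model.forward(inp, cs)
        k = 3
        loss = logits.log_softmax(-1)[0, k, seqs[0, k]]
        for p in tiny_model.parameters():
            p.grad = None
        loss.backward()
        emb_grad = tiny_model.embed.weight.grad
        future_tokens = set(seqs[0, k:].tolist()) - set(inp[0, : k + 1].tolist())
        for tok in future_tokens:
            assert np.all(emb_grad[tok] == 0.0)


class TestSampling:
    def test_one_hot_distribution_follows_argmax(self, stats, records):
        cfg = SeqModelConfig.desk(layers=1, width=32, heads=2, num_tokens=8)
        model = TokenTransformer(cfg, stats, np.random.default_rng(0))
        model.head.weight.data[:] = 0.0
        model.head.bias.data[:] = 0.0
        model.head.bias.data[5] = 1e4
        cs = conditioning_from_record(records[0])
        for seed in (0, 1, 2):
            seq = sample_sequence(cs, model, seed=seed)
            assert (seq == 5).all()

    def test_deterministic_for_seed(self, tiny_model, records):
        cs = [conditioning_from_record(r) for r in records[:3]]
        a = sample_sequence(cs, tiny_model, seed=7)
        b = sample_sequence(cs, tiny_model, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_tokens_in_range(self, tiny_model, records):
        seq = sample_sequence(conditioning_from_record(records[0]), tiny_model, seed=1)
        assert seq.min() >= 0 and seq.max() < tiny_model.cfg.num_tokens

    def test_first_token_distribution_montecarlo(self, stats, records):
        """10k draws of the first token track the predictive distribution."""
        cfg = SeqModelConfig.desk(layers=1, width=32, heads=2, num_tokens=3,
                                  grid_dims=(1, 1, 1))
        model = TokenTransformer(cfg, stats, np.random.default_rng(3))
        cs = conditioning_from_record(records[0])
        logits = next_token_logits(np.array([cfg.bos]), cs, model)[0]
        p = np.exp(logits - logits.max())
        p /= p.sum()
        csets = [cs] * 10000
        draws = sample_sequence(csets, model, seed=11)[:, 0]
        freq = np.bincount(draws, minlength=3) / draws.size
        se = np.sqrt(p * (1 - p) / draws.size)
        assert (np.abs(freq - p) < 3 * se + 1e-12).all()


class TestEnhancedRecurrence:
    def test_memory_is_next_layers_previous_output(self, stats, records):
        cfg = SeqModelConfig.desk(layers=2, width=32, heads=2, num_tokens=8,
                                  recurrence=True, cross_attention_parity=5)
        model = TokenTransformer(cfg, stats, np.random.default_rng(0))
        cs = [conditioning_from_record(records[0])]
        seq = np.array([[cfg.bos, 3]])
        _, hidden = model.forward(seq, cs, collect_hidden=True)
        mems = model.recurrence_memories(hidden)
        np.testing.assert_array_equal(mems[0].data, hidden[1].data)
        np.testing.assert_array_equal(mems[1].data, hidden[1].data)  # wraps

    def test_zero_memory_fully_masked_equals_off(self, stats, records):
        # a plumbing identity: passing no memory equals recurrence disabled
        cfg = SeqModelConfig.desk(layers=2, width=32, heads=2, num_tokens=8)
        model = TokenTransformer(cfg, stats, np.random.default_rng(0))
        cs = [conditioning_from_record(records[0])]
        seq = np.array([[cfg.bos, 3, 4]])
        base = model.forward(seq, cs).data
        again = model.forward(seq, cs, memories=[None] * cfg.layers).data
        np.testing.assert_array_equal(base, again)

    def test_two_step_toy_run_plumbing(self, stats, records):
        cfg = SeqModelConfig.desk(layers=2, width=32, heads=2, num_tokens=8,
                                  recurrence=True, cross_attention_parity=5)
        model = TokenTransformer(cfg, stats, np.random.default_rng(0))
        cs = [conditioning_from_record(records[0])]
        s0 = np.array([[cfg.bos]])
        _, h0 = model.forward(s0, cs, collect_hidden=True)
        mems = model.recurrence_memories([h.detach() for h in h0])
        s1 = np.array([[cfg.bos, 2]])
        logits_with_mem = model.forward(s1, cs, memories=mems).data
        logits_without = model.forward(s1, cs).data
        assert not np.allclose(logits_with_mem, logits_without)


class TestOverfitSanity:
    def test_memorizes_fixed_sequences(self, stats, records):
        from morphgen.seq_model.train import train_transformer_on_tokens

        cfg = SeqModelConfig.desk(layers=2, width=48, heads=4, num_tokens=16,
                                  batch_size=5, lr=0.01)
        model = TokenTransformer(cfg, stats, np.random.default_rng(1))
        seqs = np.random.default_rng(2).integers(0, 16, size=(5, cfg.sequence_length))
        csets = [conditioning_from_record(records[i]) for i in range(5)]
        log = train_transformer_on_tokens(seqs, csets, model, steps=500, seed=0)
        assert log.rows[-1]["nll"] < 0.1
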