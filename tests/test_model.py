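"""Embedding, encoder, ODE survival head, losses, training contracts."""

import math

import numpy as np
import pytest

from seqsurv import corpus, model
from seqsurv.autodiff import Tensor
from seqsurv.model import (ModelConfig, SequenceDataset, SolverError,
                           SurvivalCurve, fine_tune, init_params,
                           integrate_hazard, nll_loss, predict_risk,
                           survival_curve, train, xcal_loss)


@pytest.fixture(scope="module")
def cfg():
    return ModelConfig(embed_dim=16, n_layers=1, n_heads=2, max_len=8,
                       max_epochs=2, seed=0)


@pytest.fixture(scope="module")
def vocab():
    from datetime import date
    from tests.test_corpus import make_patient
    dates = [date(2015, 1, 1), date(2015, 2, 1), date(2015, 3, 1)]
    patients = [make_patient(dates, codes=["A00.1", "B00.2", "C00.3"],
                             pid=f"p{i}") for i in range(4)]
    return corpus.build_vocabulary(patients)


@pytest.fixture()
def params(cfg, vocab):
    return init_params(cfg, vocab, np.random.default_rng(1))


def freeze_constant_hazard(params, lam: float):
    """Force the hazard network to output exactly ``lam`` per month."""
    params["hz_W1"].data[:] = 0.0
    params["hz_b1"].data[:] = 0.0
    params["hz_W2"].data[:] = 0.0
    params["hz_b2"].data[:] = math.log(math.expm1(lam))


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def test_concat_embedding_bounded_by_tanh(params):
    ids = np.array([[3, 4, 5, 2]])
    out = model.embed(params, ids, np.ones_like(ids), np.ones_like(ids))
    assert np.all(out.data > -1.0) and np.all(out.data < 1.0)


def test_zero_projection_gives_zero_latents(params):
    params["proj_W"].data[:] = 0.0
    params["proj_b"].data[:] = 0.0
    ids = np.array([[3, 4, 5, 2]])
    out = model.embed(params, ids, np.ones_like(ids), np.ones_like(ids))
    assert np.all(out.data == 0.0)


def test_age_id_changes_concat_output(params):
    # generic (non-degenerate) age table: ids must reach the output
    params["emb_age"].data[:] = np.random.default_rng(0).normal(
        size=params["emb_age"].data.shape)
    ids = np.array([[3]])
    a1 = model.embed(params, ids, np.array([[1]]), np.array([[1]]))
    a2 = model.embed(params, ids, np.array([[2]]), np.array([[1]]))
    assert not np.allclose(a1.data, a2.data)


def test_sum_mode_is_plain_sum(params):
    ids = np.array([[3, 4]])
    ages, pos = np.array([[1, 2]]), np.array([[1, 1]])
    out = model.embed(params, ids, ages, pos, mode="sum")
    expected = (params["emb_code"].data[ids] + params["emb_age"].data[ages]
                + params["emb_pos"].data[pos])
    assert np.allclose(out.data, expected)


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------

def seq_arrays(code_ids, mask, L=6):
    codes = np.zeros((1, L), dtype=int)
    codes[0, :len(code_ids)] = code_ids
    m = np.zeros((1, L), dtype=int)
    m[0, :len(mask)] = mask
    ages = np.where(m, 2, 0)
    pos = np.where(m, 1, 0)
    return codes, ages, pos, m


def test_padding_content_is_ignored(params):
    codes, ages, pos, m = seq_arrays([3, 4, 2], [1, 1, 1])
    out1 = model.encode(params, model.embed(params, codes, ages, pos), m,
                        np.array([2]))
    codes2 = codes.copy()
    codes2[0, 4] = 5  # garbage in a padded slot
    out2 = model.encode(params, model.embed(params, codes2, ages, pos), m,
                        np.array([2]))
    assert np.allclose(out1.data, out2.data, atol=1e-12)


def test_single_predict_token_is_finite(params):
    codes, ages, pos, m = seq_arrays([2], [1])
    out = model.encode(params, model.embed(params, codes, ages, pos), m,
                       np.array([0]))
    assert np.isfinite(out.data).all()


def test_batch_composition_invariance(params, vocab):
    rng = np.random.default_rng(2)
    L = 8
    codes = rng.integers(3, vocab.n_codes, size=(3, L))
    codes[:, 5] = vocab.predict_id
    mask = np.zeros((3, L), dtype=int)
    mask[:, :6] = 1
    ages = np.where(mask, 3, 0)
    pos = np.where(mask, 1, 0)
    pidx = np.full(3, 5)
    batched = model.encode(params, model.embed(params, codes, ages, pos),
                           mask, pidx)
    solo = model.encode(params,
                        model.embed(params, codes[:1], ages[:1], pos[:1]),
                        mask[:1], pidx[:1])
    assert np.allclose(batched.data[0], solo.data[0], atol=1e-5)


def test_all_padding_errors(params):
    codes, ages, pos, m = seq_arrays([2], [1])
    with pytest.raises(ValueError, match="padding"):
        model.encode(params, model.embed(params, codes, ages, pos),
                     np.zeros_like(m), np.array([0]))


# ---------------------------------------------------------------------------
# ODE survival head
# ---------------------------------------------------------------------------

def test_survival_starts_at_one_and_is_monotone(params):
    h = np.random.default_rng(3).normal(size=params.config.embed_dim)
    times = np.linspace(0.0, 60.0, 241)
    curve = survival_curve(params, h, times)
    assert curve.survival[0] == 1.0
    assert np.all(np.diff(curve.survival) <= 1e-12)
    assert np.allclose(curve.survival, np.exp(-curve.cumhaz))
    assert np.all(curve.hazard >= 0.0)


def test_constant_hazard_closed_form(params):
    freeze_constant_hazard(params, 0.05)
    h = np.zeros(params.config.embed_dim)
    curve = survival_curve(params, h, np.array([0.0, 24.0]))
    assert curve.survival_at(24.0) == pytest.approx(math.exp(-1.2), abs=1e-4)


@pytest.mark.parametrize("shape", [1.5, 2.0, 2.5])
def test_weibull_frozen_hazard_matches_closed_form(shape):
    scale = 30.0
    lam = lambda t: (shape / scale) * np.clip(t / scale, 1e-12, None) ** (shape - 1)
    times = np.linspace(0.0, 60.0, 121)
    cum = integrate_hazard(lam, times, max_step=0.5)
    assert np.abs(cum - (times / scale) ** shape).max() <= 1e-4


def test_step_halving_check_flags_rough_hazard():
    # shape < 1 has an integrable singularity at 0 that fixed steps miss
    lam = lambda t: 0.8 / 30.0 * np.clip(t / 30.0, 1e-12, None) ** (-0.2)
    with pytest.raises(SolverError):
        integrate_hazard(lam, np.linspace(0, 60, 61), check_tolerance=1e-6)


def test_integrate_hazard_rejects_decreasing_times():
    with pytest.raises(ValueError):
        integrate_hazard(lambda t: t, np.array([1.0, 0.5]))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def constant_curve(lam, tmax=60.0):
    times = np.linspace(0, tmax, 121)
    cum = lam * times
    return SurvivalCurve(times=times, survival=np.exp(-cum), cumhaz=cum,
                         hazard=np.full_like(times, lam))


def test_nll_constant_hazard_fixture():
    curve = constant_curve(0.1)
    lab = corpus.SurvivalLabel(time=10.0, event=1)
    assert nll_loss([curve], [lab]) == pytest.approx(-math.log(0.1) + 1.0,
                                                     abs=1e-4)


def test_censored_zero_hazard_contributes_nothing():
    curve = constant_curve(0.0)
    lab = corpus.SurvivalLabel(time=10.0, event=0)
    assert nll_loss([curve], [lab]) == pytest.approx(0.0, abs=1e-12)


def test_batch_nll_is_mean_of_singles():
    curves = [constant_curve(0.1), constant_curve(0.05)]
    labels = [corpus.SurvivalLabel(10.0, 1), corpus.SurvivalLabel(24.0, 0)]
    per = [nll_loss([c], [l]) for c, l in zip(curves, labels)]
    assert nll_loss(curves, labels) == pytest.approx(np.mean(per), abs=1e-12)


def test_batch_nll_matches_closed_form_through_network(params):
    freeze_constant_hazard(params, 0.1)
    h = Tensor(np.zeros((3, params.config.embed_dim)))
    times = np.array([10.0, 5.0, 24.0])
    events = np.array([1.0, 1.0, 0.0])
    got = model._batch_nll(params, h, times, events)
    expected = np.mean([-math.log(0.1) + 1.0, -math.log(0.1) + 0.5, 2.4])
    assert float(got.data) == pytest.approx(expected, abs=1e-4)


# ---------------------------------------------------------------------------
# XCal surrogate
# ---------------------------------------------------------------------------

def test_xcal_uniform_is_near_zero_and_concentration_larger():
    F = np.arange(0.05, 1.0, 0.1)
    e = np.ones(10)
    uniform = float(xcal_loss(F, e, n_bins=10, temperature=1e4).data)
    assert uniform <= 1e-3
    concentrated = float(xcal_loss(np.full(10, 0.31), e, n_bins=10,
                                   temperature=1e4).data)
    assert concentrated > uniform


def test_xcal_permutation_invariant_and_input_validated():
    rng = np.random.default_rng(4)
    F = rng.uniform(size=30)
    e = rng.integers(0, 2, 30).astype(float)
    a = float(xcal_loss(F, e).data)
    perm = rng.permutation(30)
    b = float(xcal_loss(F[perm], e[perm]).data)
    assert a == pytest.approx(b, abs=1e-12)
    with pytest.raises(ValueError):
        xcal_loss(np.array([1.2]), np.array([1.0]))


def test_xcal_censoring_spreads_mass_above_F():
    # a patient censored at F=0 contributes 1/B to every bin: exactly uniform
    F = np.zeros(5)
    e = np.zeros(5)
    val = float(xcal_loss(F, e, n_bins=10, temperature=1e4).data)
    assert val == pytest.approx(0.0, abs=1e-6)


# ---------------------------------------------------------------------------
# training contracts
# ---------------------------------------------------------------------------

def test_training_is_deterministic_and_alpha_zero_matches_noxcal(
        small_dataset, small_vocab):
    base = dict(embed_dim=16, n_layers=1, n_heads=2, max_len=64,
                max_epochs=2, seed=5)
    p1, h1 = train(small_dataset, ModelConfig(use_xcal=False, **base),
                   small_vocab)
    p2, h2 = train(small_dataset, ModelConfig(use_xcal=False, **base),
                   small_vocab)
    assert h1[-1].train_loss == h2[-1].train_loss
    assert h1[-1].eval_loss == h2[-1].eval_loss
    p3, h3 = train(small_dataset,
                   ModelConfig(use_xcal=True, xcal_weight=0.0, **base),
                   small_vocab)
    assert h3[-1].train_loss == pytest.approx(h1[-1].train_loss, abs=1e-12)
    for k in p1.tensors:
        assert np.array_equal(p1[k].data, p3[k].data)


def test_training_requires_examples(small_vocab, cfg):
    empty = SequenceDataset(*[np.zeros((1, 4), dtype=int)] * 4,
                            np.zeros(1, dtype=int), np.ones(1), np.ones(1))
    with pytest.raises(ValueError):
        train(empty, cfg, small_vocab)


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------

def test_fine_tune_zero_epochs_is_identity(small_dataset, small_vocab):
    cfg0 = ModelConfig(embed_dim=16, n_layers=1, n_heads=2, max_len=64,
                       max_epochs=0, seed=6)
    pre = init_params(cfg0, small_vocab, np.random.default_rng(7))
    out, history = fine_tune(pre, small_dataset, cfg0, small_vocab, small_vocab)
    assert history == []
    for k in pre.tensors:
        assert np.array_equal(out[k].data, pre[k].data)


def test_fine_tune_copies_shared_code_embeddings(vocab, cfg):
    pre = init_params(cfg, vocab, np.random.default_rng(8))
    # new vocabulary missing one code, adding another
    codes = {c: i for i, c in enumerate(corpus.SPECIAL_TOKENS)}
    for c in ("A00.1", "Z99.9"):
        codes[c] = len(codes)
    vocab_new = corpus.Vocabulary(code_to_id=codes, age_min=vocab.age_min,
                                  age_max=vocab.age_max,
                                  max_position=vocab.max_position)
    cfg0 = ModelConfig(**{**cfg.__dict__, "max_epochs": 0})
    out, _ = fine_tune(pre, None, cfg0, vocab, vocab_new)
    assert np.array_equal(out["emb_code"].data[codes["A00.1"]],
                          pre["emb_code"].data[vocab.code_to_id["A00.1"]])
    assert out["emb_code"].data.shape[0] == len(codes)
    assert np.array_equal(out["proj_W"].data, pre["proj_W"].data)


def test_fine_tune_rejects_incompatible_architecture(vocab, cfg):
    pre = init_params(cfg, vocab, np.random.default_rng(9))
    bad = ModelConfig(**{**cfg.__dict__, "embed_dim": 32, "n_heads": 2})
    with pytest.raises(ValueError, match="incompatible"):
        fine_tune(pre, None, bad, vocab, vocab)


# ---------------------------------------------------------------------------
# risk prediction
# ---------------------------------------------------------------------------

def make_tiny_dataset(vocab, n=4, L=8):
    rng = np.random.default_rng(10)
    codes = rng.integers(3, vocab.n_codes, size=(n, L))
    mask = np.zeros((n, L), dtype=int)
    mask[:, :3] = 1
    codes[:, 2] = vocab.predict_id
    return SequenceDataset(
        code_ids=codes, age_ids=np.where(mask, 2, 0),
        position_ids=np.where(mask, 1, 0), attention_mask=mask,
        predict_index=np.full(n, 2), times=np.full(n, 12.0),
        events=np.ones(n))


def test_risk_zero_horizon_and_monotone(params, vocab):
    ds = make_tiny_dataset(vocab)
    assert np.all(predict_risk(params, ds, horizon=0.0) == 0.0)
    r12 = predict_risk(params, ds, horizon=12.0)
    r36 = predict_risk(params, ds, horizon=36.0)
    assert np.all(r36 >= r12 - 1e-12)
    assert np.all((r36 >= 0) & (r36 <= 1))


def test_frozen_hazard_risk_closed_form(params, vocab):
    freeze_constant_hazard(params, 0.05)
    ds = make_tiny_dataset(vocab)
    risks = predict_risk(params, ds, horizon=24.0)
    assert np.allclose(risks, 1.0 - math.exp(-1.2), atol=1e-4)


def test_checkpoint_save_load_round_trip(tmp_path, params):
    params.save(tmp_path / "ckpt")
    back = model.ModelParams.load(tmp_path / "ckpt")
    assert back.config == params.config
    for k, t in params.tensors.items():
        assert np.array_equal(back[k].data, t.data)
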