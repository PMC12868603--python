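import numpy as np
import pytest

from seqsurv import corpus, model, simulate


def make_dataset(records, truths, vocab, study_end, max_len=64):
    truth_by_id = {g.patient_id: g for g in truths}
    examples, pids = [], []
    for rec in records:
        g = truth_by_id[rec.patient_id]
        seq = corpus.build_sequence(rec, g.index_date, vocab, max_len=max_len)
        lab = corpus.label_example(rec, g.index_date, study_end)
        examples.append((seq, lab))
        pids.append(rec.patient_id)
    return model.SequenceDataset.from_examples(examples, pids)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = simulate.default_config(n_patients=300, seed=42)
    records, truths = simulate.simulate_cohort(cfg)
    return cfg, records, truths


@pytest.fixture(scope="session")
def small_vocab(small_cohort):
    _, records, _ = small_cohort
    return corpus.build_vocabulary(records)


@pytest.fixture(scope="session")
def small_dataset(small_cohort, small_vocab):
    cfg, records, truths = small_cohort
    return make_dataset(records, truths, small_vocab, cfg.study_end)


@pytest.fixture(scope="session")
def tiny_trained(small_cohort, small_vocab, small_dataset):
    """A small model trained briefly on the shared cohort; reused by the
    survival-head, attribution and acceptance tests."""
    mcfg = model.ModelConfig(embed_dim=16, n_layers=1, n_heads=2, max_len=64,
                             max_epochs=6, seed=3, learning_rate=3e-3,
                             patience=6)
    params, history = model.train(small_dataset, mcfg, small_vocab)
    return params, history
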