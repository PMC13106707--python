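import pytest
from hypothesis import settings

import fitrx as fx

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
from fitrx.preprocess import tensorize


@pytest.fixture(scope="session")
def cohort_600():
    """A 600-subject cohort with the default skewed class mix."""
    recs = fx.generate_cohort(fx.CohortSpec(n=600, seed=11))
    X, y = fx.records_to_compact(recs)
    return recs, X, y


@pytest.fixture(scope="session")
def tiny_cfg():
    """A small extractor configuration for fast structural/gradient tests."""
    return fx.ExtractorConfig(
        conv_filters=(6, 8, 8), heads=2, attn_dropout=0.0,
        hidden_noise=0.0, max_epochs=2, batch_size=32, seed=5,
    )


@pytest.fixture(scope="session")
def trained_tiny(cohort_600, tiny_cfg):
    """A tiny extractor trained for two epochs on fold 0 of the cohort."""
    _, X, y = cohort_600
    plan = fx.make_folds(X, y, n_folds=5, seed=3)
    f0 = plan.folds[0]
    model, hist = fx.train_extractor(
        tensorize(f0.X_train), f0.y_train, tensorize(f0.X_val), f0.y_val, tiny_cfg
    )
    return model, hist, f0
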