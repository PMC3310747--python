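import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def study():
    """A small training/evaluation study shared across tests: classifiers
    fitted on 428 synthetic training spectra (default charge distribution)
    with CP+NL and CP-only features, plus a held-out test set."""
    import etdprep as e

    spectra, truths = e.generate_dataset(2428, seed=428)
    tr_s, tr_t, te_s, te_t = e.train_test_split(spectra, truths, 428, seed=428)
    ytr = np.array([t.charge for t in tr_t])
    yte = np.array([t.charge for t in te_t])
    ext = e.ChargeFeatureExtractor().fit(tr_s)
    ext_cp = e.ChargeFeatureExtractor(include_nl=False).fit(tr_s)
    clf = e.LinearDiscriminantChargeClassifier().fit(ext.transform(tr_s), ytr)
    clf_cp = e.LinearDiscriminantChargeClassifier().fit(
        ext_cp.transform(tr_s), ytr)
    return {
        "train_spectra": tr_s, "train_charges": ytr,
        "test_spectra": te_s, "test_charges": yte,
        "extractor": ext, "classifier": clf,
        "extractor_cp_only": ext_cp, "classifier_cp_only": clf_cp,
    }
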