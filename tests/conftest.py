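import numpy as np
import pytest

from vocalrisk.features import PatientFeatures
from vocalrisk.synth import VoiceParams, standardize_clip, synthesize_vowel


@pytest.fixture(scope="session")
def clean_clip():
    """Zero-perturbation phonation: F0 125 Hz (integer period at 16 kHz),
    no jitter/shimmer/drift, near-noiseless."""
    params = VoiceParams(f0=125.0, jitter_pct=0.0, shimmer_pct=0.0,
                         target_hnr_db=60.0, drift_pct=0.0, seed=1)
    return standardize_clip(synthesize_vowel(params))


@pytest.fixture(scope="session")
def typical_clip():
    """Mildly perturbed phonation typical of the low-risk group."""
    params = VoiceParams(f0=140.0, jitter_pct=1.0, shimmer_pct=3.0,
                         target_hnr_db=20.0, seed=7)
    return standardize_clip(synthesize_vowel(params))


def make_feature_cohort(n_high, n_low, rng, signal_features=("f0", "f1"),
                        shift=1.0, n_features=10, site="dev",
                        age_gap=8.0):
    """Feature-level synthetic cohort (no audio): Gaussian features with a
    planted mean shift on the signal features for high-risk patients."""
    names = [f"f{k}" for k in range(n_features)]
    out = []
    for i in range(n_high + n_low):
        hi = i < n_high
        feats = {}
        for name in names:
            mu = shift if (hi and name in signal_features) else 0.0
            feats[name] = float(rng.normal(mu, 1.0))
        out.append(PatientFeatures(
            patient_id=f"{site}{i}",
            age=float(rng.normal(63.0 + (age_gap if hi else 0.0), 10.0)),
            sex="male" if rng.random() < (0.8 if hi else 0.45) else "female",
            risk_label="high" if hi else "low",
            features=feats))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
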