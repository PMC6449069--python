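"""Shared fixtures: configs, synthetic records and cached cohorts."""

from __future__ import annotations

import numpy as np
import pytest

import mfvepcad as m
from mfvepcad.records import N_CHANNELS, N_SAMPLES, N_SECTORS


@pytest.fixture(scope="session")
def cfg() -> m.PipelineConfig:
    return m.PipelineConfig()


def make_record(signal: np.ndarray, subject_id: str = "S1", eye: str = "OD",
                label: str = "Controls") -> m.MfVEPRecord:
    return m.MfVEPRecord(subject_id=subject_id, eye=eye, label=label,
                         signal=signal)


def noise_record(rng: np.random.Generator, sd: float = 1.0, **kw) -> m.MfVEPRecord:
    return make_record(rng.normal(0.0, sd, size=(N_SECTORS, N_CHANNELS, N_SAMPLES)),
                       **kw)


def make_features(subject_id: str, eye: str, label: str, values,
                  i_sv: int = 0, mean_snr: float = 3.0) -> m.EyeFeatures:
    """Wrap a raw vector into an EyeFeatures for classifier tests."""
    values = np.asarray(values, dtype=float)
    assert values.size == 6 * (4 + i_sv)
    return m.EyeFeatures(subject_id=subject_id, eye=eye, label=label,
                         i_sv=i_sv, values=values, mean_snr=mean_snr,
                         nas_total=0)


@pytest.fixture(scope="session")
def cohort30():
    """Default-calibrated cohort, 30 eyes per class, seed 1, with features."""
    spec = m.SimSpec(n_eyes_per_group={g: 30 for g in m.EYE_CLASSES}, seed=1)
    cohort = m.simulate_cohort(spec)
    feats = m.extract_cohort_features(cohort.records, template=cohort.template,
                                      cfg=m.PipelineConfig())
    return cohort, feats


@pytest.fixture(scope="session")
def exaggerated_cohort():
    """Strongly separated cohort (effect multiplier 5), 20 eyes/class, seed 2."""
    spec = m.SimSpec(n_eyes_per_group={g: 20 for g in m.EYE_CLASSES}, seed=2,
                     profiles=m.scaled_profiles(5.0))
    cohort = m.simulate_cohort(spec)
    feats = m.extract_cohort_features(cohort.records, template=cohort.template,
                                      cfg=m.PipelineConfig())
    return cohort, feats
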