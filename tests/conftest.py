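import numpy as np
import pytest

from ctctrack.expression import ExpressionSample, calibrate_thresholds
from ctctrack.panel import CT_MAX, default_panel
from ctctrack.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture
def make_sample(panel):
    """Factory: a patient sample with given Ct values, rest undetected."""

    def _make(ct=None, sample_id="S1", patient_id="P1", visit=1, rbc_lysis=True):
        ct = dict(ct or {})
        for g in panel.symbols:
            ct.setdefault(g, CT_MAX)
        return ExpressionSample(
            sample_id=sample_id,
            patient_id=patient_id,
            visit=visit,
            rbc_lysis=rbc_lysis,
            ct=ct,
            panel=panel,
        )

    return _make


@pytest.fixture
def make_hd_samples(panel):
    """Factory: HD samples in one arm with a given expression level per gene.

    ``levels`` is a list of per-sample expression values applied to every
    gene (Ct = 40 - level).
    """

    def _make(levels, rbc_lysis=True, prefix="HD"):
        out = []
        for i, level in enumerate(levels):
            ct = {g: CT_MAX - level for g in panel.symbols}
            out.append(
                ExpressionSample(
                    sample_id=f"{prefix}{i}",
                    patient_id=f"{prefix}{i}",
                    visit=None,
                    rbc_lysis=rbc_lysis,
                    ct=ct,
                    panel=panel,
                )
            )
        return out

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_patients=80), seed=42)


@pytest.fixture(scope="session")
def small_thresholds(small_cohort):
    return calibrate_thresholds(small_cohort.hd_samples)
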