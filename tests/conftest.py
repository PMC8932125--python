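import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prodromes import (
    Cohort,
    Diagnosis,
    Dimension,
    GeneratorSpec,
    PatientRecord,
    SymptomCatalog,
    SymptomDefinition,
    builtin_catalog,
    generate_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return builtin_catalog()


@pytest.fixture(scope="session")
def published_cohort():
    """Synthetic cohort at the published group sizes and prevalences."""
    return generate_cohort(GeneratorSpec(seed=1))


def make_catalog(prevs_sz, prevs_msd, with_onset=True):
    """Small ad-hoc catalog; symptom names exercise CSV quoting."""
    defs = []
    for i, (psz, pmsd) in enumerate(zip(prevs_sz, prevs_msd)):
        kwargs = {}
        if with_onset:
            kwargs = dict(
                onset_mean_sz=12.0 + i, onset_sd_sz=2.0,
                onset_mean_msd=11.0 + i, onset_sd_msd=2.5,
            )
        defs.append(
            SymptomDefinition(
                name=f"symptom {i}, test",
                dimension=Dimension.other,
                prev_sz=psz,
                prev_msd=pmsd,
                **kwargs,
            )
        )
    return SymptomCatalog(defs)


def cohort_from_counts(a, b, c, d, name="s", onsets=None):
    """Single-symptom cohort realising the 2x2 table (a, b, c, d).

    ``onsets`` optionally maps group -> list of onset ages for positives.
    """
    catalog = SymptomCatalog(
        [SymptomDefinition(name=name, dimension=Dimension.other,
                           prev_sz=a / (a + b) if a + b else 0.0,
                           prev_msd=c / (c + d) if c + d else 0.0)]
    )
    onsets = onsets or {}
    patients = []
    k = 0
    for diag, pos, neg in ((Diagnosis.SZ, a, b), (Diagnosis.MSD, c, d)):
        ages = list(onsets.get(diag, []))
        for i in range(pos):
            onset = {name: ages[i]} if i < len(ages) else {}
            patients.append(
                PatientRecord(f"p{k}", diag, {name: 1}, onset)
            )
            k += 1
        for _ in range(neg):
            patients.append(PatientRecord(f"p{k}", diag, {name: 0}, {}))
            k += 1
    return Cohort(patients, catalog)


@pytest.fixture
def rng():
    return np.random.default_rng(20220318)
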