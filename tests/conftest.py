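import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import histomil as hm

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-mix cohort shared by read-only tests."""
    cfg = hm.SyntheticConfig(n_patients=24, tiles_per_slide=(30, 60), seed=3)
    return hm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def gated_small(small_cohort):
    """Latent-gated bags + slide labels of the small cohort."""
    co = small_cohort
    by_slide = dict(tuple(co.tiles.groupby("slide_id", sort=False)))
    gated = []
    for b in co.slides:
        keep = np.flatnonzero(by_slide[b.slide_id]["neoplastic"].to_numpy() == 1)
        gated.append(b.subset(keep))
    labels = {p.patient_id: p.label for p in co.patients}
    y = np.array([labels[b.patient_id] for b in gated], dtype=float)
    return gated, y


def latent_gate(cohort):
    by_slide = dict(tuple(cohort.tiles.groupby("slide_id", sort=False)))
    return [b.subset(np.flatnonzero(
        by_slide[b.slide_id]["neoplastic"].to_numpy() == 1))
        for b in cohort.slides]
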