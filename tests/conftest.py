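import numpy as np
import pytest

from icnmhe import (
    SimulationConfig,
    analysis_mask,
    dual_regress,
    simulate_cohort,
)
from icnmhe.cohort import default_planted_effect, make_template_set


SMALL = dict(
    n_mhe=8, n_nmhe=10, grid_shape=(14, 16, 14), n_templates=3, n_timepoints=40
)


@pytest.fixture(scope="session")
def small_templates():
    return make_template_set(3, (14, 16, 14), seed=5)


@pytest.fixture(scope="session")
def planted_cohort():
    """Small cohort with a fully separable planted deficit in network 0."""
    cfg = SimulationConfig(**SMALL, seed=2)
    templates, scans, records = simulate_cohort(cfg)
    return cfg, templates, scans, records


@pytest.fixture(scope="session")
def planted_zmaps(planted_cohort):
    """z-map stacks per network plus labels for the planted cohort."""
    cfg, templates, scans, records = planted_cohort
    mask = analysis_mask(templates)
    stacks = {name: [] for name in templates.names}
    for scan, rec in zip(scans, records):
        maps = dual_regress(scan, templates, subject_id=rec.subject_id, mask=mask)
        for k, name in enumerate(templates.names):
            stacks[name].append(maps.z[k])
    zmaps = {name: np.stack(v) for name, v in stacks.items()}
    labels = np.array([r.group == "MHE" for r in records])
    planted = default_planted_effect(templates)
    return zmaps, labels, mask, planted
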