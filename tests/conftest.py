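from dataclasses import replace

import pytest

from ergop.simulate import PRESETS, CohortConfig, generate_cohort, preset


def noise_free(params):
    return replace(params, noise_sd_uV=0.0, drift_sd_uV=0.0)


@pytest.fixture(scope="session")
def nf_presets():
    """Noise-free versions of the four group x condition presets."""
    return {name: noise_free(p) for name, p in PRESETS.items()}


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """A small deterministic DA10 cohort written to disk (2 + 2 subjects)."""
    out = tmp_path_factory.mktemp("cohort")
    config = CohortConfig(2, 2, "DA10", 1000.0, preset("control", "DA10"),
                          preset("achm", "DA10"), between_subject_cv=0.1, seed=7)
    manifest = generate_cohort(config, str(out))
    return out, manifest, config
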