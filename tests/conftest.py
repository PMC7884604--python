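import numpy as np
import pytest

from restconn.denoise import CleanRun
from restconn.synthetic import CohortSpec, generate_bold_run, generate_cohort


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """Desk-scale cohort: small grid and shortened runs for fast tests."""
    return CohortSpec(n_lean=8, n_obese=6, n_volumes_acquired=160, n_discard=5,
                      grid_shape=(12, 12, 12), rng_seed=7)


@pytest.fixture(scope="session")
def still_spec(tiny_spec) -> CohortSpec:
    """Tiny cohort with motion spikes disabled (clean traces)."""
    import dataclasses
    return dataclasses.replace(tiny_spec, spike_rate=0.0)


@pytest.fixture(scope="session")
def still_run(still_spec):
    """One spike-free run from the tiny cohort."""
    rec = generate_cohort(still_spec)[0]
    return generate_bold_run(rec, "T0", still_spec)


def as_clean(run) -> CleanRun:
    """Wrap a raw run as an all-retained CleanRun for correlation tests."""
    return CleanRun(residuals=run.data,
                    retained=np.ones(run.n_volumes, dtype=bool),
                    band=(0.01, 0.1), tr_s=run.tr_s, affine=run.affine)
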