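import pytest

from spectralcal.phantom import (
    build_study_specs,
    generate_phantom,
    study_roi_specs,
)
from spectralcal.roi import extract_measurements


@pytest.fixture(scope="session")
def noiseless_iodine_study():
    """12 noiseless iodine configurations: (spec, manifest, measurements)."""
    out = []
    for spec in build_study_specs("iodine", seed=7, noise_sd=(0.0, 0.0)):
        pair, manifest = generate_phantom(spec)
        measurements = extract_measurements(pair, study_roi_specs(manifest))
        out.append((spec, manifest, measurements))
    return out


@pytest.fixture(scope="session")
def noiseless_iron_study():
    out = []
    for spec in build_study_specs("iron", seed=11, noise_sd=(0.0, 0.0)):
        pair, manifest = generate_phantom(spec)
        measurements = extract_measurements(pair, study_roi_specs(manifest))
        out.append((spec, manifest, measurements))
    return out
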