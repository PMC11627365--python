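import numpy as np
import pytest

from parmap import cortex, synthetic


@pytest.fixture(scope="session")
def polarized_embryo():
    """One noiseless two-protein embryo (nominal composite asymmetry 0.6)."""
    spec = synthetic.polarized_embryo_spec(asi=0.6, dosage=1.0, noise_sd=0.0, seed=1)
    image, truth = synthetic.render_embryo(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def segmented_embryo(polarized_embryo):
    _, image, truth = polarized_embryo
    contour = cortex.segment_embryo(image, channel="apar", anterior_marker="apar")
    return image, truth, contour


@pytest.fixture(scope="session")
def fitted_profiles(segmented_embryo):
    image, truth, contour = segmented_embryo
    profiles = {}
    for role in ("apar", "ppar"):
        st = cortex.straighten_cortex(image, contour, channel=role)
        profiles[role] = cortex.fit_membrane_profiles(st)
    return image, truth, contour, profiles


def membrane_profile_from_amplitude(s, amplitude, cytoplasm=50.0):
    """Wrap an analytic amplitude trace as a fitted-profile object."""
    n = len(s)
    return cortex.MembraneProfile(
        s=np.asarray(s, float),
        amplitude=np.asarray(amplitude, float),
        cytoplasm=np.full(n, float(cytoplasm)),
        center_um=np.zeros(n),
        ridge_width_um=0.5,
        edge_width_um=0.5,
        offset=0.0,
        residual_rms=np.zeros(n),
        flagged=np.zeros(n, dtype=bool),
    )
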