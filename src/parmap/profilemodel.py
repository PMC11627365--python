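"""The cross-membrane intensity model shared by renderer and fitter.

A linescan taken perpendicular to the cell cortex (coordinate ``x`` in
microns, increasing from outside to inside the embryo) is modelled as

    I(x) = A * exp(-(x - c)^2 / (2 w_g^2))             (membrane ridge)
         + (C / 2) * (1 + erf((x - c) / (w_e sqrt(2))))  (cytoplasm step)
         + O                                            (flat offset)

with a shared centre ``c``: the membrane ridge sits on the cytoplasm
boundary, so the Gaussian peak and the erf inflection coincide. ``A`` is
the membrane concentration readout, ``C`` the cytoplasmic plateau.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf


def gauss_erf_profile(x, amplitude, cytoplasm, center, ridge_width, edge_width, offset=0.0):
    """Evaluate the Gaussian + error-function membrane/cytoplasm model."""
    x = np.asarray(x, dtype=float)
    d = x - center
    gauss = amplitude * np.exp(-(d**2) / (2.0 * ridge_width**2))
    step = 0.5 * cytoplasm * (1.0 + erf(d / (edge_width * np.sqrt(2.0))))
    return gauss + step + offset


def interior_step(signed_distance, edge_width):
    """Smooth interior indicator: 1 deep inside, 0 outside, 0.5 on the boundary.

    ``signed_distance`` is positive inside the embryo, in microns.
    """
    return 0.5 * (1.0 + erf(np.asarray(signed_distance, float) / (edge_width * np.sqrt(2.0))))
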