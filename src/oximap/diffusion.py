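"""Closed-form diffuse reflectance of a homogeneous turbid slab under
spatially modulated illumination.

The forward model is the standard spatially resolved diffusion
approximation: reflectance is a rational function of the ratio between
the scalar attenuation at the projected spatial frequency and the total
transport coefficient, with an extrapolated-boundary term derived from
the refractive-index mismatch.  It is accurate for transport albedos
typical of soft tissue (``musp/mua`` of roughly 10 or more) and is used
both to render synthetic acquisitions and to fill inversion lookup
tables.  Any callable with the same signature can be substituted when
building a table (e.g. a Monte Carlo surrogate).
"""

from __future__ import annotations

import numpy as np

__all__ = ["effective_reflection_coefficient", "diffuse_reflectance"]


def effective_reflection_coefficient(n_index: float) -> float:
    """Effective internal reflection coefficient for a tissue/air boundary.

    Polynomial fit in the relative refractive index, valid for
    ``n_index`` in roughly [1.0, 1.6].
    """
    n = float(n_index)
    return 0.0636 * n + 0.668 + 0.710 / n - 1.440 / n**2


def diffuse_reflectance(mua, musp, fx=0.0, n_index: float = 1.4):
    """Diffuse reflectance ``Rd`` at spatial frequency ``fx``.

    Parameters
    ----------
    mua, musp : float or ndarray
        Absorption and reduced scattering coefficients, mm^-1.
        Must be strictly positive.
    fx : float or ndarray
        Spatial frequency of the illumination pattern, mm^-1 (>= 0).
    n_index : float
        Tissue refractive index, expected in [1.3, 1.5].

    Returns
    -------
    float or ndarray
        Dimensionless diffuse reflectance in (0, 1); strictly decreasing
        in both ``mua`` and ``fx``.
    """
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    fx = np.asarray(fx, dtype=float)
    if np.any(mua <= 0) or np.any(musp <= 0):
        raise ValueError("optical properties must be strictly positive")
    if np.any(fx < 0):
        raise ValueError("spatial frequency must be non-negative")
    if not (1.3 <= n_index <= 1.5):
        raise ValueError(f"refractive index {n_index} outside supported [1.3, 1.5]")

    mutr = mua + musp
    albedo = musp / mutr
    mueff = np.sqrt(3.0 * mua * mutr)
    # scalar attenuation at the projection frequency
    mueff_fx = np.sqrt(mueff**2 + (2.0 * np.pi * fx) ** 2)
    reff = effective_reflection_coefficient(n_index)
    a_boundary = (1.0 - reff) / (2.0 * (1.0 + reff))
    ratio = mueff_fx / mutr
    rd = 3.0 * a_boundary * albedo / ((ratio + 1.0) * (ratio + 3.0 * a_boundary))
    return rd if rd.ndim else float(rd)
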