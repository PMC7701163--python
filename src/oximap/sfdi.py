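"""Multi-frame structured-illumination processing: three-phase
demodulation, reference calibration, lookup-table inversion of diffuse
reflectance to optical properties, linear chromophore fitting, and
oxygen-saturation computation.

This is the conventional (ground-truth) pipeline: six frames per
wavelength (two spatial frequencies, three phase offsets) are demodulated
and calibrated against a reference phantom, the DC/AC reflectance pair is
inverted per pixel through a precomputed table, absorption at all
wavelengths is fit to the chromophore basis, and saturation is the oxy
fraction of total hemoglobin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.optimize import nnls as scipy_nnls
from scipy.spatial import Delaunay, cKDTree

from .chromophores import ChromophoreBasis
from .diffusion import diffuse_reflectance

__all__ = [
    "ModulationPair",
    "OpticalPropertyMap",
    "ReflectanceLUT",
    "ConcentrationMaps",
    "StO2Map",
    "demodulate_three_phase",
    "calibrate",
    "build_lut",
    "invert_lut",
    "fit_chromophores",
    "compute_sto2",
    "sfdi_ground_truth",
]

THREE_PHASES = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)


@dataclass
class ModulationPair:
    """Demodulated AC and DC magnitudes (detector units) at one wavelength."""

    mac: np.ndarray
    mdc: np.ndarray
    wavelength: float
    fx: float

    def __post_init__(self):
        if self.mac.shape != self.mdc.shape:
            raise ValueError("MAC/MDC shape mismatch")


@dataclass
class OpticalPropertyMap:
    """Per-pixel absorption and reduced scattering (mm^-1) at one wavelength."""

    mua: np.ndarray
    musp: np.ndarray
    wavelength: float
    valid: np.ndarray

    def __post_init__(self):
        if not (self.mua.shape == self.musp.shape == self.valid.shape):
            raise ValueError("map shape mismatch")


@dataclass
class ConcentrationMaps:
    c_oxy: np.ndarray
    c_deoxy: np.ndarray
    residual: np.ndarray


@dataclass
class StO2Map:
    """Oxygen saturation in [0, 1] with a validity mask."""

    sto2: np.ndarray
    valid: np.ndarray


def demodulate_three_phase(i1: np.ndarray, i2: np.ndarray, i3: np.ndarray):
    """Recover (MAC, MDC) from three frames phase-shifted by 2*pi/3.

    For per-pixel ``I_k = A + B*cos(theta + phi_k)`` with the standard
    phase set, ``MAC = (sqrt(2)/3) * sqrt((I1-I2)^2 + (I2-I3)^2 +
    (I3-I1)^2)`` equals ``B`` and ``MDC = (I1+I2+I3)/3`` equals ``A``.
    """
    i1, i2, i3 = (np.asarray(x, dtype=float) for x in (i1, i2, i3))
    if not (i1.shape == i2.shape == i3.shape):
        raise ValueError("phase frames must share one shape")
    mac = (np.sqrt(2.0) / 3.0) * np.sqrt(
        (i1 - i2) ** 2 + (i2 - i3) ** 2 + (i3 - i1) ** 2
    )
    mdc = (i1 + i2 + i3) / 3.0
    return mac, mdc


def calibrate(m_sample: np.ndarray, m_ref: np.ndarray, rd_ref_model: float):
    """Convert demodulated magnitude to diffuse reflectance.

    ``Rd = (M_sample / M_ref) * Rd_ref_model`` — detector gain and the
    illumination profile are common to both magnitudes and cancel.
    Non-positive reference pixels yield NaN (flagged, not raised).
    """
    if not (0.0 < rd_ref_model < 1.0):
        raise ValueError("reference model reflectance must lie in (0, 1)")
    m_sample = np.asarray(m_sample, dtype=float)
    m_ref = np.asarray(m_ref, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rd = np.where(m_ref > 0, m_sample / m_ref, np.nan) * rd_ref_model
    return rd


@dataclass
class ReflectanceLUT:
    """Forward table (mua, musp) -> (Rd_dc, Rd_ac) plus its inverse interpolant.

    Grids are log-spaced.  Inversion interpolates (log mua, log musp)
    linearly over the Delaunay triangulation of the forward samples in
    (Rd_dc, Rd_ac) space; out-of-gamut queries fall back to the nearest
    grid node and are flagged invalid.
    """

    mua_grid: np.ndarray
    musp_grid: np.ndarray
    rd_dc: np.ndarray
    rd_ac: np.ndarray
    fx_ac: float
    n_index: float
    _interp_mua: object = field(default=None, repr=False, compare=False)
    _interp_musp: object = field(default=None, repr=False, compare=False)
    _tree: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        for table in (self.rd_dc, self.rd_ac):
            if np.any(table <= 0) or np.any(table >= 1):
                raise ValueError("reflectance tables must lie strictly in (0, 1)")

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.rd_dc.ravel(), self.rd_ac.ravel()])

    @property
    def node_log_optics(self) -> np.ndarray:
        gm, gs = np.meshgrid(self.mua_grid, self.musp_grid, indexing="ij")
        return np.column_stack([np.log(gm.ravel()), np.log(gs.ravel())])

    def _build_inverse(self):
        pts = self.points
        logs = self.node_log_optics
        tri = Delaunay(pts)
        self._interp_mua = LinearNDInterpolator(tri, logs[:, 0])
        self._interp_musp = LinearNDInterpolator(tri, logs[:, 1])
        self._tree = cKDTree(pts)

    def ensure_inverse(self):
        if self._interp_mua is None:
            self._build_inverse()


def build_lut(
    forward: Callable = diffuse_reflectance,
    mua_bounds=(0.001, 0.5),
    musp_bounds=(0.2, 5.0),
    n_mua: int = 256,
    n_musp: int = 256,
    fx_ac: float = 0.2,
    n_index: float = 1.4,
) -> ReflectanceLUT:
    """Fill DC/AC reflectance tables on a log-spaced optics grid.

    ``forward(mua, musp, fx, n_index)`` is evaluated at ``fx = 0`` and
    ``fx = fx_ac``.  Injectivity of the forward map on the grid is
    checked with a nearest-neighbor collision test; collisions are
    reported as a build error.
    """
    mua_grid = np.geomspace(*mua_bounds, n_mua)
    musp_grid = np.geomspace(*musp_bounds, n_musp)
    gm, gs = np.meshgrid(mua_grid, musp_grid, indexing="ij")
    rd_dc = np.asarray(forward(gm, gs, 0.0, n_index))
    rd_ac = np.asarray(forward(gm, gs, fx_ac, n_index))
    lut = ReflectanceLUT(mua_grid, musp_grid, rd_dc, rd_ac, fx_ac, n_index)

    pts = lut.points
    tree = cKDTree(pts)
    dist, idx = tree.query(pts, k=2)
    scale = max(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)), 1.0)
    collisions = np.flatnonzero(dist[:, 1] < 1e-12 * scale)
    if collisions.size:
        pairs = [(int(i), int(idx[i, 1])) for i in collisions[:10]]
        raise ValueError(f"forward map not injective on grid; colliding nodes {pairs}")
    lut._tree = tree
    return lut


def invert_lut(
    rd_dc: np.ndarray,
    rd_ac: np.ndarray,
    lut: ReflectanceLUT,
    wavelength: float = float("nan"),
    method: str = "linear",
) -> OpticalPropertyMap:
    """Per-pixel (mua, musp) from a (DC, AC) reflectance pair.

    ``method='linear'`` interpolates within the table gamut and flags
    out-of-gamut or non-finite pixels invalid, filling them with the
    nearest grid node.  ``method='nearest'`` snaps every pixel to its
    nearest node (exact on node inputs).
    """
    rd_dc = np.asarray(rd_dc, dtype=float)
    rd_ac = np.asarray(rd_ac, dtype=float)
    if rd_dc.shape != rd_ac.shape:
        raise ValueError("reflectance images must share one shape")
    lut.ensure_inverse()
    shape = rd_dc.shape
    queries = np.column_stack([rd_dc.ravel(), rd_ac.ravel()])
    finite = np.all(np.isfinite(queries), axis=1)
    queries_safe = np.where(finite[:, None], queries, 0.0)
    logs = lut.node_log_optics

    if method == "nearest":
        _, nearest = lut._tree.query(queries_safe)
        log_mua = logs[nearest, 0]
        log_musp = logs[nearest, 1]
        valid = finite.copy()
    elif method == "linear":
        log_mua = lut._interp_mua(queries_safe)
        log_musp = lut._interp_musp(queries_safe)
        inside = np.isfinite(log_mua) & np.isfinite(log_musp)
        valid = finite & inside
        if not np.all(valid):
            _, nearest = lut._tree.query(queries_safe[~valid])
            log_mua[~valid] = logs[nearest, 0]
            log_musp[~valid] = logs[nearest, 1]
    else:
        raise ValueError(f"unknown inversion method {method!r}")

    return OpticalPropertyMap(
        mua=np.exp(log_mua).reshape(shape),
        musp=np.exp(log_musp).reshape(shape),
        wavelength=wavelength,
        valid=valid.reshape(shape),
    )


def _nnls_two_columns(e: np.ndarray, mua: np.ndarray):
    """Vectorized non-negative least squares for a 2-column basis.

    The unconstrained normal-equation solution is used wherever it is
    already non-negative; otherwise the optimum lies on a boundary face
    (one concentration clamped to zero) and the better of the two
    single-column fits is taken.
    """
    w, _ = e.shape
    gram_inv = np.linalg.inv(e.T @ e)
    c = mua @ (gram_inv @ e.T).T  # (P, 2)
    neg = np.any(c < 0, axis=1)
    if np.any(neg):
        sub = mua[neg]  # (Q, W)
        cands = np.zeros((sub.shape[0], 2, 2))
        resid = np.empty((sub.shape[0], 2))
        for j in range(2):
            col = e[:, j]
            cj = np.clip(sub @ col / (col @ col), 0.0, None)
            cands[:, j, j] = cj
            resid[:, j] = np.linalg.norm(sub - np.outer(cj, col), axis=1)
        pick = np.argmin(resid, axis=1)
        c[neg] = cands[np.arange(sub.shape[0]), pick]
    fitted = c @ e.T
    residual = np.linalg.norm(mua - fitted, axis=1)
    return c, residual


def fit_chromophores(
    mua_stack: Sequence[OpticalPropertyMap] | np.ndarray,
    basis: ChromophoreBasis,
    wavelengths: Sequence[float] | None = None,
) -> ConcentrationMaps:
    """Per-pixel non-negative least-squares fit of the absorption mixture.

    ``mua_stack`` is either a sequence of :class:`OpticalPropertyMap`
    (wavelengths taken from the maps) or a raw ``(W, H, W)`` array with
    ``wavelengths`` given explicitly.  With two chromophores the
    non-negative solution is computed in closed form; larger bases fall
    back to an iterative per-pixel solver.
    """
    if wavelengths is None:
        maps = list(mua_stack)
        wavelengths = [m.wavelength for m in maps]
        images = np.stack([m.mua for m in maps])
    else:
        images = np.asarray(mua_stack, dtype=float)
    if images.shape[0] < 2:
        raise ValueError("need at least two wavelengths to fit chromophores")
    e = basis.submatrix(wavelengths)  # raises if rank deficient
    shape = images.shape[1:]
    mua = images.reshape(images.shape[0], -1).T  # (P, W)

    if len(basis.names) == 2:
        c, residual = _nnls_two_columns(e, mua)
    else:
        c = np.empty((mua.shape[0], len(basis.names)))
        residual = np.empty(mua.shape[0])
        for p in range(mua.shape[0]):
            c[p], residual[p] = scipy_nnls(e, mua[p])

    return ConcentrationMaps(
        c_oxy=c[:, basis.oxy_column].reshape(shape),
        c_deoxy=c[:, basis.deoxy_column].reshape(shape),
        residual=residual.reshape(shape),
    )


def compute_sto2(conc: ConcentrationMaps, min_total: float = 1e-6) -> StO2Map:
    """Oxygen saturation ``c_oxy / (c_oxy + c_deoxy)``.

    Pixels with total hemoglobin below ``min_total`` are invalid (avoids
    0/0); values are clamped to [0, 1] where valid.
    """
    total = conc.c_oxy + conc.c_deoxy
    valid = total >= min_total
    with np.errstate(divide="ignore", invalid="ignore"):
        sto2 = np.where(valid, conc.c_oxy / np.where(valid, total, 1.0), 0.0)
    return StO2Map(sto2=np.clip(sto2, 0.0, 1.0), valid=valid)


def _dc_magnitude(stack, wavelength):
    """Mean of the planar (fx = 0) frames at one wavelength."""
    frames = stack.triplet(wavelength, 0.0)
    return np.mean([f.intensity for f in frames], axis=0)


def _ac_magnitudes(stack, wavelength, fx):
    frames = stack.triplet(wavelength, fx)
    mac, mdc = demodulate_three_phase(*(f.intensity for f in frames))
    return mac, mdc


def sfdi_ground_truth(
    stack,
    ref,
    lut: ReflectanceLUT,
    basis: ChromophoreBasis,
    min_total: float = 1e-6,
    return_details: bool = False,
):
    """Full conventional pipeline: demodulate, calibrate, invert, fit.

    ``stack`` must contain the complete protocol (every wavelength at
    fx = 0 and at the AC frequency, three phases each); ``ref`` is a
    rendered reference phantom matching the protocol.  The DC arm uses
    the mean of the three planar frames; the AC arm uses the demodulated
    magnitude of the ``fx_ac`` triplet.
    """
    fx_ac = lut.fx_ac
    wavelengths = sorted(stack.wavelengths())
    missing = []
    for wl in wavelengths:
        for fx in (0.0, fx_ac):
            for phase in THREE_PHASES:
                if not stack.has(wl, fx, phase):
                    missing.append((wl, fx, round(phase, 6)))
    if missing:
        raise ValueError(f"stack missing protocol frames: {missing}")

    optics = []
    for wl in wavelengths:
        mdc_sample = _dc_magnitude(stack, wl)
        mac_sample, _ = _ac_magnitudes(stack, wl, fx_ac)
        mdc_ref = _dc_magnitude(ref.stack, wl)
        mac_ref, _ = _ac_magnitudes(ref.stack, wl, fx_ac)
        rd_dc = calibrate(mdc_sample, mdc_ref, ref.rd_model[(wl, 0.0)])
        rd_ac = calibrate(mac_sample, mac_ref, ref.rd_model[(wl, fx_ac)])
        optics.append(invert_lut(rd_dc, rd_ac, lut, wavelength=wl))

    conc = fit_chromophores(optics, basis)
    sto2 = compute_sto2(conc, min_total=min_total)
    sto2.valid &= np.all([m.valid for m in optics], axis=0)
    if return_details:
        return sto2, optics, conc
    return sto2
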