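"""Chromophore extinction spectra and the absorption basis used for
concentration fitting.

Absorption is modeled as a linear mixture: ``mua(lam_i) = sum_n
eps_n(lam_i) * c_n`` where ``eps`` is the extinction coefficient of
chromophore ``n`` at wavelength ``lam_i`` and ``c_n`` its concentration.
The packaged table covers oxy- and deoxy-hemoglobin at the four
near-infrared wavelengths used by the default acquisition protocol; it
is plain CSV and user-replaceable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ChromophoreBasis", "OXY", "DEOXY", "load_default_basis"]

OXY = "oxyhemoglobin"
DEOXY = "deoxyhemoglobin"


@dataclass(frozen=True)
class ChromophoreBasis:
    """Extinction-coefficient matrix over a wavelength grid.

    Attributes
    ----------
    wavelengths : ndarray, shape (W,)
        Strictly increasing wavelengths, nm.
    names : tuple of str
        Chromophore names; must include oxy- and deoxy-hemoglobin.
    epsilon : ndarray, shape (W, N)
        Extinction coefficients, mm^-1 per unit concentration.
        Rows follow ``wavelengths``, columns follow ``names``.
    """

    wavelengths: np.ndarray
    names: tuple
    epsilon: np.ndarray
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        eps = np.asarray(self.epsilon, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "epsilon", eps)
        object.__setattr__(self, "names", tuple(self.names))
        if wl.ndim != 1 or eps.shape != (wl.size, len(self.names)):
            raise ValueError("epsilon must be (n_wavelengths, n_chromophores)")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(eps <= 0):
            raise ValueError("extinction coefficients must be positive")
        for required in (OXY, DEOXY):
            if required not in self.names:
                raise ValueError(f"basis must include {required!r}")
        object.__setattr__(self, "_index", {w: i for i, w in enumerate(wl)})

    def row(self, wavelength: float) -> np.ndarray:
        """Extinction coefficients at one wavelength (exact match)."""
        try:
            return self.epsilon[self._index[float(wavelength)]]
        except KeyError:
            raise KeyError(
                f"wavelength {wavelength} nm not in basis {self.wavelengths.tolist()}"
            ) from None

    def submatrix(self, wavelengths) -> np.ndarray:
        """Extinction submatrix for a wavelength subset, checked full rank."""
        sub = np.stack([self.row(w) for w in wavelengths])
        if np.linalg.matrix_rank(sub) < len(self.names):
            raise ValueError(
                f"extinction submatrix at {list(wavelengths)} nm is rank deficient"
            )
        return sub

    @property
    def oxy_column(self) -> int:
        return self.names.index(OXY)

    @property
    def deoxy_column(self) -> int:
        return self.names.index(DEOXY)

    @classmethod
    def from_csv(cls, path) -> "ChromophoreBasis":
        table = pd.read_csv(path, comment="#")
        cols = [c for c in table.columns if c != "wavelength_nm"]
        names = [c.removeprefix("epsilon_") for c in cols]
        rename = {"oxy": OXY, "deoxy": DEOXY}
        names = [rename.get(n, n) for n in names]
        return cls(
            wavelengths=table["wavelength_nm"].to_numpy(float),
            names=tuple(names),
            epsilon=table[cols].to_numpy(float),
        )


def load_default_basis() -> ChromophoreBasis:
    """Packaged oxy/deoxy-hemoglobin table at {659, 691, 731, 851} nm."""
    ref = resources.files("oximap.data") / "hemoglobin_extinction.csv"
    with resources.as_file(ref) as path:
        return ChromophoreBasis.from_csv(Path(path))
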