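"""Evaluation metrics, masking rules, and convolution receptive-field
arithmetic."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .sfdi import StO2Map

__all__ = ["EvaluationReport", "nmae", "pooled_nmae", "receptive_field", "occlusion_trend"]


@dataclass
class EvaluationReport:
    """Normalized mean absolute error over masked pixels."""

    nmae: float
    n_pixels: int
    per_region: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.nmae < 0 or self.n_pixels <= 0:
            raise ValueError("invalid evaluation report")


def _as_map(x) -> StO2Map:
    if isinstance(x, StO2Map):
        return x
    arr = np.asarray(x, dtype=float)
    return StO2Map(sto2=arr, valid=np.ones(arr.shape, dtype=bool))


def nmae(
    pred,
    truth,
    mask: np.ndarray | None = None,
    regions: dict | None = None,
    method: str = "",
) -> EvaluationReport:
    """``sum(|pred - truth|) / sum(truth)`` over the intersection of the
    supplied mask and both validity masks.

    Accepts :class:`~oximap.sfdi.StO2Map` or bare arrays.  ``regions``
    optionally maps region names to boolean masks for a breakdown.
    """
    pred = _as_map(pred)
    truth = _as_map(truth)
    if pred.sto2.shape != truth.sto2.shape:
        raise ValueError("prediction/truth shape mismatch")
    effective = pred.valid & truth.valid
    if mask is not None:
        if mask.shape != pred.sto2.shape:
            raise ValueError("mask shape mismatch")
        effective &= mask.astype(bool)
    if not np.any(effective):
        raise ValueError("empty effective mask")
    denom = float(np.sum(truth.sto2[effective]))
    if denom == 0.0:
        raise ValueError("truth sums to zero over the mask; NMAE undefined")
    value = float(np.sum(np.abs(pred.sto2[effective] - truth.sto2[effective])) / denom)

    per_region = {}
    if regions:
        for name, rmask in regions.items():
            sel = effective & rmask.astype(bool)
            if np.any(sel) and np.sum(truth.sto2[sel]) > 0:
                per_region[name] = float(
                    np.sum(np.abs(pred.sto2[sel] - truth.sto2[sel]))
                    / np.sum(truth.sto2[sel])
                )
    return EvaluationReport(
        nmae=value,
        n_pixels=int(np.sum(effective)),
        per_region=per_region,
        provenance={"method": method},
    )


def pooled_nmae(pairs: Sequence[Tuple], mask=None) -> EvaluationReport:
    """Pool pixels from several (pred, truth) map pairs into one NMAE.

    Pooling applies the error formula over the union of all pixels (the
    primary aggregate); a per-pair breakdown is included for reference.
    """
    num = 0.0
    den = 0.0
    n = 0
    per = {}
    for i, (pred, truth) in enumerate(pairs):
        rep = nmae(pred, truth, mask=mask)
        truth_map = _as_map(truth)
        pred_map = _as_map(pred)
        eff = pred_map.valid & truth_map.valid
        if mask is not None:
            eff &= mask.astype(bool)
        num += float(np.sum(np.abs(pred_map.sto2[eff] - truth_map.sto2[eff])))
        den += float(np.sum(truth_map.sto2[eff]))
        n += int(np.sum(eff))
        per[f"pair_{i}"] = rep.nmae
    if den == 0.0:
        raise ValueError("pooled truth sums to zero")
    per["mean_of_pairs"] = float(np.mean([v for k, v in per.items() if k.startswith("pair_")]))
    return EvaluationReport(nmae=num / den, n_pixels=n, per_region=per)


def receptive_field(layers: Sequence[Tuple[int, int]]) -> int:
    """One-side receptive field of a stack of (kernel, stride) layers.

    Forward recursion: ``r += (k - 1) * jump; jump *= stride`` — exact
    integer, independent of channel widths.
    """
    if not layers:
        raise ValueError("empty layer list")
    r, jump = 1, 1
    for kernel, stride in layers:
        r += (kernel - 1) * jump
        jump *= stride
    return r


def occlusion_trend(series, region: np.ndarray) -> pd.DataFrame:
    """Mean saturation over ``region`` (intersected with validity) per
    time point, as a (time_s, mean_sto2) table."""
    if not np.any(region):
        raise ValueError("empty region of interest")
    rows = []
    for t, sto2_map in series:
        m = _as_map(sto2_map)
        sel = region.astype(bool) & m.valid
        if not np.any(sel):
            raise ValueError(f"region has no valid pixels at t={t}")
        rows.append({"time_s": float(t), "mean_sto2": float(np.mean(m.sto2[sel]))})
    return pd.DataFrame(rows)
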