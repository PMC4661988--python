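"""Quantitative comparison of velocity fields: SER, energies, divergence.

The signal-to-error ratio (SER, dB) treats the reference field as the
ground-truth signal and the estimate's deviation from it as the error:

    SER = 10 log10( sum ||v_ref||^2 / sum ||v_est - v_ref||^2 )

computed over a comparison mask (by default the lumen FLUID cells, which
avoids zero-padding bias from the rectangular box), overall and per
component.  Identical fields give an explicit +inf sentinel, never a
floating-point overflow.
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np

from .grid import GridSpec, LumenMask, StaggeredVelocityField, divergence

__all__ = ["SERReport", "ser", "component_energy_ratio", "divergence_stats"]

INF_SENTINEL = math.inf


@dataclasses.dataclass
class SERReport:
    """Per-component and overall SER (dB) plus reference component energies."""

    ser_u: float
    ser_v: float
    ser_w: float
    ser_total: float
    energy_u: float
    energy_v: float
    energy_w: float
    n_voxels: int

    def to_dict(self) -> dict:
        def enc(x):
            if math.isinf(x):
                return "inf" if x > 0 else "-inf"
            return x
        return {k: enc(v) for k, v in dataclasses.asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "SERReport":
        def dec(x):
            if x == "inf":
                return math.inf
            if x == "-inf":
                return -math.inf
            return x
        return cls(**{k: dec(v) for k, v in d.items()})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "SERReport":
        return cls.from_dict(json.loads(s))

    def row(self, label: str = "") -> str:
        def fmt(x):
            return "  +inf" if math.isinf(x) else f"{x:6.2f}"
        return (f"{label:<12s} {fmt(self.ser_u)} {fmt(self.ser_v)} "
                f"{fmt(self.ser_w)} {fmt(self.ser_total)}")


def _db_ratio(num: float, den: float) -> float:
    if den == 0.0:
        return INF_SENTINEL
    if num == 0.0:
        return -INF_SENTINEL
    return 10.0 * math.log10(num / den)


def ser(est_components, ref_components, mask) -> SERReport:
    """SER of an estimated cell-centered 3-component field vs a reference.

    ``est_components`` and ``ref_components`` are (u, v, w) triples of
    equally shaped volumes; ``mask`` is the boolean comparison region
    (treating the reference as the ground-truth signal).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("comparison mask is empty")
    sig = err = 0.0
    per = []
    energies = []
    for e, r in zip(est_components, ref_components):
        e = np.asarray(e)
        r = np.asarray(r)
        if e.shape != r.shape or e.shape != mask.shape:
            raise ValueError("field/mask shape mismatch")
        s = float(np.sum(r[mask] ** 2))
        d = float(np.sum((e[mask] - r[mask]) ** 2))
        per.append(_db_ratio(s, d))
        energies.append(s)
        sig += s
        err += d
    if sig == 0.0:
        raise ValueError("reference field has zero energy on the mask")
    return SERReport(per[0], per[1], per[2], _db_ratio(sig, err),
                     energies[0], energies[1], energies[2],
                     int(mask.sum()))


def component_energy_ratio(ref_components, mask) -> dict:
    """Pairwise component energy ratios in dB over the mask.

    Returns e.g. ``{"w/u": 11.4, "w/v": 15.7, "u/v": ...}``; a zero-energy
    denominator yields the +inf sentinel, a zero-energy numerator -inf.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("comparison mask is empty")
    e = [float(np.sum(np.asarray(c)[mask] ** 2)) for c in ref_components]
    names = "uvw"
    out = {}
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            out[f"{names[a]}/{names[b]}"] = _db_ratio(e[a], e[b])
    return out


def divergence_stats(field: StaggeredVelocityField, grid: GridSpec,
                     mask) -> dict:
    """Max and RMS of the discrete divergence (1/s) over a cell mask."""
    sel = np.asarray(mask.fluid if isinstance(mask, LumenMask) else mask,
                     dtype=bool)
    if not sel.any():
        raise ValueError("divergence mask is empty")
    div = divergence(field, grid)[sel]
    return {
        "max_abs": float(np.max(np.abs(div))),
        "rms": float(np.sqrt(np.mean(div ** 2))),
        "n_cells": int(sel.sum()),
    }
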