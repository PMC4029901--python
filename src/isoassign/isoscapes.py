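"""Calibration of environmental isoscapes into feather isoscapes.

Environmental surfaces predict the isotopic composition of precipitation
(d2H) or plants (d13C, d15N); feathers grown at a location differ from
those pools systematically.  Calibration maps each environmental surface
to a feather-equivalent surface:

* d2H: an affine regression transfer function ``d2H_f = slope * d2H_p +
  intercept`` fitted externally on birds of known origin.  The slope and
  intercept are **mandatory configuration** — there is no defensible
  default, so none is supplied.
* d13C and d15N: a constant trophic discrimination offset added to the
  plant surface (+2 permil for d13C, +5 permil for d15N by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .grids import IsoscapeStack, RasterGrid, align_stack

__all__ = [
    "CalibrationSpec",
    "calibrate_d2h",
    "apply_discrimination",
    "calibrate_stack",
]


class CalibrationError(ValueError):
    """Raised when calibration parameters are missing or invalid."""


@dataclass(frozen=True)
class CalibrationSpec:
    """Transfer-function parameters mapping environmental to feather values.

    ``d2h_slope`` and ``d2h_intercept`` have no defaults and must come from
    an external feather-vs-precipitation regression.  Discrimination
    offsets default to the standard plant-to-feather values (+2 permil for
    d13C, +5 permil for d15N).
    """

    d2h_slope: float
    d2h_intercept: float
    d13c_discrimination: float = 2.0
    d15n_discrimination: float = 5.0

    def __post_init__(self) -> None:
        for name in ("d2h_slope", "d2h_intercept", "d13c_discrimination", "d15n_discrimination"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise CalibrationError(f"{name} must be a finite number, got {v!r}")
        if self.d2h_slope == 0:
            raise CalibrationError("d2h_slope must be nonzero")

    @classmethod
    def from_mapping(cls, cfg: Mapping[str, float]) -> "CalibrationSpec":
        if "d2h_slope" not in cfg or "d2h_intercept" not in cfg:
            raise CalibrationError(
                "d2h_slope and d2h_intercept are required calibration settings "
                "(no default exists; supply the feather-vs-precipitation regression)"
            )
        return cls(
            d2h_slope=float(cfg["d2h_slope"]),
            d2h_intercept=float(cfg["d2h_intercept"]),
            d13c_discrimination=float(cfg.get("d13c_discrimination", 2.0)),
            d15n_discrimination=float(cfg.get("d15n_discrimination", 5.0)),
        )


def calibrate_d2h(precip: RasterGrid, spec: CalibrationSpec) -> RasterGrid:
    """Affine map of a precipitation d2H surface to a feather d2H surface.

    Every valid cell v becomes ``slope * v + intercept``; the validity mask
    is unchanged.
    """
    return precip.with_values(spec.d2h_slope * precip.values + spec.d2h_intercept)


def apply_discrimination(plant: RasterGrid, offset: float) -> RasterGrid:
    """Add a constant trophic discrimination offset (permil) to a surface."""
    if not np.isfinite(offset):
        raise CalibrationError(f"discrimination offset must be finite, got {offset!r}")
    return plant.with_values(plant.values + offset)


def calibrate_stack(
    environmental: Mapping[str, RasterGrid], spec: CalibrationSpec
) -> IsoscapeStack:
    """Calibrate environmental layers into an aligned feather isoscape stack.

    ``environmental`` maps isotope names to raw surfaces: the d2H layer is
    a precipitation surface, d13C/d15N are plant surfaces.
    """
    layers: dict[str, RasterGrid] = {}
    provenance: dict[str, str] = {}
    if "d2H" in environmental:
        layers["d2H"] = calibrate_d2h(environmental["d2H"], spec)
        provenance["d2H"] = (
            f"precipitation d2H; affine feather calibration "
            f"slope={spec.d2h_slope} intercept={spec.d2h_intercept}"
        )
    if "d13C" in environmental:
        layers["d13C"] = apply_discrimination(environmental["d13C"], spec.d13c_discrimination)
        provenance["d13C"] = f"plant d13C; discrimination {spec.d13c_discrimination:+g} permil"
    if "d15N" in environmental:
        layers["d15N"] = apply_discrimination(environmental["d15N"], spec.d15n_discrimination)
        provenance["d15N"] = f"plant d15N; discrimination {spec.d15n_discrimination:+g} permil"
    return align_stack(layers, provenance=provenance)
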