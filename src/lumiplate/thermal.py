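"""First-order estimate of medium temperature rise during stimulation.

The LED matrix dissipates heat while driven, and the culture medium
warms toward a plateau; longer and more frequent stimulation produces a
larger rise.  This module models that with the simplest consistent
form, a single-exponential relaxation:

    dT(t) = gain_K * duty * (1 - exp(-t / tau_s))

where ``duty`` is the LED duty cycle over the schedule and ``tau_s``
the thermal time constant.  The default tau of 1200 s puts the curve at
>= 95 % of its plateau after one hour, matching the observed plateau
time scale.  The plateau gain has no hardware-anchored default and must
be supplied from the user's own measurement.

This is an order-of-magnitude estimate for schedule screening, not a
spatially resolved heat-transfer simulation.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass
from typing import Sequence

__all__ = ["ThermalModel", "ThermalError", "temp_rise", "temp_curve", "curve_to_csv"]


class ThermalError(ValueError):
    pass


@dataclass(frozen=True)
class ThermalModel:
    """gain_K: plateau temperature rise (K) at duty 1; tau_s: time constant."""

    gain_K: float = 1.0
    tau_s: float = 1200.0

    def __post_init__(self) -> None:
        if self.gain_K < 0:
            raise ThermalError("gain_K must be >= 0")
        if self.tau_s <= 0:
            raise ThermalError("tau_s must be positive")


def temp_rise(t_s: float, duty: float, model: ThermalModel | None = None) -> float:
    """Temperature rise (K) after t seconds at the given duty cycle."""
    model = model or ThermalModel()
    if not 0.0 <= duty <= 1.0:
        raise ThermalError(f"duty cycle {duty} outside [0, 1]")
    if t_s < 0:
        raise ThermalError(f"negative time {t_s}")
    return model.gain_K * duty * (1.0 - math.exp(-t_s / model.tau_s))


def temp_curve(
    times_s: Sequence[float], duty: float, model: ThermalModel | None = None
) -> list[float]:
    return [temp_rise(t, duty, model) for t in times_s]


def curve_to_csv(
    times_s: Sequence[float], duty: float, model: ThermalModel | None = None
) -> str:
    out = io.StringIO()
    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(["t_s", "delta_T_K"])
    for t, dt in zip(times_s, temp_curve(times_s, duty, model)):
        writer.writerow([t, f"{dt:.6g}"])
    return out.getvalue()
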