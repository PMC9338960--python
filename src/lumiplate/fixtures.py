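"""Seeded program generators and packaged stimulation protocols.

``random_program`` draws syntactically and semantically valid programs
for property testing; ``builtin_protocols`` loads the csv protocols
shipped with the package, which replicate the stimulation schedules
used in the device's characterization experiments:

* ``pulse_train_phase_shift`` — two pairs of 96-well wells pulsed 3 s
  every 5 min over 1 h, the second pair phase-shifted by 30 min.
* ``staggered_fixation_12pt`` — a 10-s pulse staggered over 12 wells at
  2-min resolution so all wells are fixed simultaneously at the end.
* ``single_pulse_fixation_ladder`` — a single 2-s pulse staggered at
  1-min resolution for high-time-resolution fixation series.
* ``pulse_train_high_freq`` / ``pulse_train_low_freq`` — 10-s pulses
  every 2 min (42 pulses) or every 20 min (5 pulses) over 84 min, the
  sustained-versus-pulsatile signalling comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .geometry import Column, PlateFormat, Row, Well, default_registry
from .program import Color, Command, Program, parse_program

__all__ = ["ProtocolPreset", "FixtureError", "random_program", "builtin_protocols"]

_PRESET_FILES = (
    "pulse_train_phase_shift",
    "staggered_fixation_12pt",
    "single_pulse_fixation_ladder",
    "pulse_train_high_freq",
    "pulse_train_low_freq",
)

_PRESET_NOTES = {
    "pulse_train_phase_shift": (
        "3-s blue pulses every 5 min for 1 h in wells A01/B01; same "
        "pattern delayed by 30 min in C01/D01"
    ),
    "staggered_fixation_12pt": (
        "10-s blue pulse staggered over 12 wells at 2-min resolution; "
        "all stimulation-to-fixation intervals end together"
    ),
    "single_pulse_fixation_ladder": (
        "single 2-s blue pulse staggered over 12 wells at 1-min "
        "resolution for a high-resolution fixation series"
    ),
    "pulse_train_high_freq": (
        "10-s blue pulses every 2 min over 84 min (42 pulses): "
        "high-frequency train evoking sustained pathway activity"
    ),
    "pulse_train_low_freq": (
        "10-s blue pulses every 20 min over 84 min (5 pulses): "
        "low-frequency train evoking discrete activity pulses"
    ),
}


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class ProtocolPreset:
    name: str
    program: Program
    note: str
    plate_format: str


def builtin_protocols() -> list[ProtocolPreset]:
    """Load the packaged csv protocols (each valid on its stated plate)."""
    presets = []
    for name in _PRESET_FILES:
        text = (
            resources.files("lumiplate").joinpath(f"presets/{name}.csv").read_text()
        )
        program = parse_program(text)
        presets.append(
            ProtocolPreset(
                name=name,
                program=program,
                note=_PRESET_NOTES[name],
                plate_format=program.plate_format,
            )
        )
    return presets


def random_program(
    seed: int,
    n_commands: int,
    plate: str | PlateFormat = "96-well",
    max_start_s: int = 600,
    max_duration_s: int = 30,
    max_repeats: int = 4,
    max_extra_interval_s: int = 120,
) -> Program:
    """Draw a random valid program, deterministic for a given seed.

    Targets are wells, rows and columns of the plate format; timing
    respects the 1-s minimum pulse and non-self-overlapping repeats, so
    every generated program passes validation on a default placement.
    """
    if n_commands < 0:
        raise FixtureError("n_commands must be >= 0")
    if max_duration_s < 1 or max_start_s < 0 or max_repeats < 1:
        raise FixtureError("unsatisfiable constraints")
    fmt = plate if isinstance(plate, PlateFormat) else default_registry()[plate]
    rng = np.random.default_rng(seed)
    commands = []
    for _ in range(n_commands):
        kind = rng.choice(["well", "well", "well", "row", "column"])
        if kind == "well":
            r = int(rng.integers(0, fmt.n_well_rows))
            c = int(rng.integers(0, fmt.n_well_cols))
            target = Well(f"{chr(ord('A') + r)}{c + 1:02d}")
        elif kind == "row":
            target = Row(chr(ord("A") + int(rng.integers(0, fmt.n_well_rows))))
        else:
            target = Column(int(rng.integers(0, fmt.n_well_cols)) + 1)
        duration = int(rng.integers(1, max_duration_s + 1))
        start = int(rng.integers(0, max_start_s + 1))
        repeats = int(rng.integers(1, max_repeats + 1))
        interval = 0
        if repeats > 1:
            interval = duration + int(rng.integers(0, max_extra_interval_s + 1))
        color = Color(
            red=int(rng.integers(0, 256)) if rng.random() < 0.3 else 0,
            green=int(rng.integers(0, 256)) if rng.random() < 0.3 else 0,
            blue=int(rng.integers(1, 256)),
        )
        commands.append(
            Command(
                target=target,
                start_s=start,
                duration_s=duration,
                color=color,
                repeat_count=repeats,
                repeat_interval_s=interval,
            )
        )
    return Program(
        commands=commands, name=f"random-{seed}", plate_format=fmt.name
    )
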