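"""Compile programs into event lists and 1 Hz frame timelines.

The firmware's minimum pulse is 1 s, so the timeline is quantized to
whole seconds: a compiled program is a sparse map from second to a
32 x 64 x 3 intensity grid, an absent second meaning all-off.  Event
intervals are half-open ``[t_on, t_off)`` — a 3 s pulse lights exactly
3 frames.

When two commands claim the same LED in the same second, each channel
takes the maximum of the competing intensities.  The maximum is
idempotent and order-independent, and unlike additive blending it can
neither exceed the 255 hardware ceiling nor fabricate light dose.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .geometry import LedSet, MatrixSpec, Placement, Well, resolve_target
from .program import Color, Command, Program

__all__ = [
    "Event",
    "FrameTimeline",
    "EmulatorAction",
    "SchedulerError",
    "expand",
    "build_timeline",
    "compile_program",
    "duty_cycle",
    "reverse_schedule",
    "emulate",
]


class SchedulerError(ValueError):
    pass


@dataclass(frozen=True)
class Event:
    """One contiguous illumination interval of one LED set."""

    led_set: LedSet
    t_on_s: int
    t_off_s: int
    color: Color
    source_command: int

    def __post_init__(self) -> None:
        if self.t_off_s - self.t_on_s < 1:
            raise SchedulerError(
                f"event [{self.t_on_s}, {self.t_off_s}) shorter than 1 s"
            )


class FrameTimeline:
    """Sparse per-second sequence of intensity grids.

    ``frames`` maps a second to a (n_rows, n_cols, 3) uint8 grid;
    seconds with every LED off are not stored.
    """

    def __init__(self, horizon_s: int, matrix: MatrixSpec | None = None):
        self.matrix = matrix or MatrixSpec()
        self.horizon_s = int(horizon_s)
        self.frames: dict[int, np.ndarray] = {}

    def frame_at(self, t: int) -> np.ndarray:
        """Grid at second t (zeros when all-off or out of horizon)."""
        f = self.frames.get(t)
        if f is None:
            return np.zeros((self.matrix.n_rows, self.matrix.n_cols, 3), dtype=np.uint8)
        return f

    @property
    def lit_seconds(self) -> list[int]:
        return sorted(self.frames)

    def lit_led_seconds(self) -> int:
        """Total number of (LED, second) pairs with any nonzero channel."""
        return int(sum(np.any(f > 0, axis=2).sum() for f in self.frames.values()))

    # -- exports ------------------------------------------------------------

    def to_sparse_csv(self) -> str:
        """Per-second dump: one line per lit LED (t,row,col,r,g,b)."""
        out = io.StringIO()
        writer = csv.writer(out, lineterminator="\n")
        writer.writerow(["t", "row", "col", "red", "green", "blue"])
        for t in self.lit_seconds:
            frame = self.frames[t]
            rows, cols = np.nonzero(np.any(frame > 0, axis=2))
            for r, c in zip(rows.tolist(), cols.tolist()):
                writer.writerow([t, r, c, *frame[r, c].tolist()])
        return out.getvalue()

    def snapshot_png(self, t: int, path, scale: int = 8) -> None:
        """Write the frame at second t as a PNG image."""
        from PIL import Image

        frame = self.frame_at(t)
        img = Image.fromarray(frame, mode="RGB")
        img = img.resize(
            (frame.shape[1] * scale, frame.shape[0] * scale), Image.NEAREST
        )
        img.save(path)

    def preview_text(self, t: int) -> str:
        """Plain-text rendering of one frame ('#' lit, '.' off)."""
        frame = self.frame_at(t)
        lit = np.any(frame > 0, axis=2)
        return "\n".join(
            "".join("#" if lit[r, c] else "." for c in range(frame.shape[1]))
            for r in range(frame.shape[0])
        ) + "\n"


@dataclass(frozen=True)
class EmulatorAction:
    """One device-side action during playback."""

    time_s: int
    kind: str  # frame_change | message_show | countdown_tick | buzzer
    payload: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------


def expand(
    program: Program,
    placement: Placement | None = None,
    matrix: MatrixSpec | None = None,
) -> list[Event]:
    """Expand every command's repetition loop into concrete events.

    Pulse k (0-based) of a command starts at ``start + k*interval``;
    each command's target is resolved to LEDs exactly once.  Events are
    returned sorted by on-time.
    """
    matrix = matrix or MatrixSpec()
    events: list[Event] = []
    for i, cmd in enumerate(program.commands):
        leds = resolve_target(cmd.target, placement, matrix)
        for t_on in cmd.pulse_starts():
            events.append(
                Event(
                    led_set=leds,
                    t_on_s=t_on,
                    t_off_s=t_on + cmd.duration_s,
                    color=cmd.color,
                    source_command=i,
                )
            )
    events.sort(key=lambda e: (e.t_on_s, e.source_command))
    return events


def build_timeline(
    events: Sequence[Event], matrix: MatrixSpec | None = None
) -> FrameTimeline:
    """Rasterize events into the sparse 1 Hz timeline.

    Per second, per LED, per channel the intensity is the channel-wise
    maximum over all events covering that second; seconds in which
    every LED is off are left absent.
    """
    matrix = matrix or MatrixSpec()
    horizon = max((e.t_off_s for e in events), default=0)
    timeline = FrameTimeline(horizon, matrix)
    if not events:
        return timeline
    for event in events:
        if event.color.is_off or not event.led_set:
            continue
        rows = np.fromiter((r for r, _ in event.led_set), dtype=np.intp)
        cols = np.fromiter((c for _, c in event.led_set), dtype=np.intp)
        color = np.array(event.color.as_tuple(), dtype=np.uint8)
        for t in range(event.t_on_s, event.t_off_s):
            frame = timeline.frames.get(t)
            if frame is None:
                frame = np.zeros(
                    (matrix.n_rows, matrix.n_cols, 3), dtype=np.uint8
                )
                timeline.frames[t] = frame
            frame[rows, cols] = np.maximum(frame[rows, cols], color)
    # drop any frame that ended up all-off (defensive; cannot happen above)
    for t in [t for t, f in timeline.frames.items() if not f.any()]:
        del timeline.frames[t]
    return timeline


def compile_program(
    program: Program,
    placement: Placement | None = None,
    matrix: MatrixSpec | None = None,
) -> FrameTimeline:
    """expand + build_timeline in one call."""
    matrix = matrix or MatrixSpec()
    return build_timeline(expand(program, placement, matrix), matrix)


def duty_cycle(
    timeline: FrameTimeline, led: tuple[int, int], window: tuple[int, int]
) -> float:
    """Fraction of seconds in ``[t0, t1)`` with any channel on at `led`.

    Duty cycle drives both light dose and matrix heating.
    """
    t0, t1 = window
    if t1 <= t0:
        raise SchedulerError(f"empty duty-cycle window [{t0}, {t1})")
    if t0 < 0 or t1 > timeline.horizon_s:
        raise SchedulerError(
            f"window [{t0}, {t1}) outside timeline horizon {timeline.horizon_s}"
        )
    r, c = led
    on = 0
    for t in range(t0, t1):
        frame = timeline.frames.get(t)
        if frame is not None and frame[r, c].any():
            on += 1
    return on / (t1 - t0)


def reverse_schedule(
    time_points_s: Sequence[int],
    pulse: Command,
    wells: Sequence[str],
    horizon_s: int | None = None,
) -> Program:
    """Stagger pulses so all wells reach a common endpoint together.

    ``time_points_s[k]`` is the requested interval between the start of
    well k's stimulation and the shared end of the experiment, so the
    whole plate can be fixed simultaneously: well k's pulse starts at
    ``horizon - time_points_s[k]``.
    """
    if len(time_points_s) != len(wells):
        raise SchedulerError(
            f"{len(time_points_s)} time points for {len(wells)} wells"
        )
    horizon = horizon_s if horizon_s is not None else max(time_points_s, default=0)
    commands = []
    for tp, well in zip(time_points_s, wells):
        if tp > horizon:
            raise SchedulerError(f"time point {tp} s exceeds horizon {horizon} s")
        if tp < pulse.duration_s:
            raise SchedulerError(
                f"time point {tp} s shorter than the {pulse.duration_s} s pulse"
            )
        commands.append(
            replace(
                pulse,
                target=Well(well),
                start_s=horizon - tp,
                repeat_count=1,
                repeat_interval_s=0,
            )
        )
    return Program(
        commands=commands, name="reverse-schedule", fixation_horizon_s=horizon
    )


def emulate(timeline: FrameTimeline, program: Program) -> list[EmulatorAction]:
    """Replay the device-side behaviour of a compiled program.

    Emits a ``frame_change`` at every second where the displayed grid
    differs from the previous second; for each command carrying a
    message, a ``message_show`` at its start, a ``countdown_tick`` every
    second until the deadline (start + duration), and a ``buzzer`` at
    the deadline when flagged.
    """
    actions: list[EmulatorAction] = []
    prev = timeline.frame_at(-1)  # all-off before t=0
    for t in range(0, timeline.horizon_s + 1):
        frame = timeline.frame_at(t)
        if not np.array_equal(frame, prev):
            actions.append(
                EmulatorAction(
                    t,
                    "frame_change",
                    {"lit_leds": int(np.any(frame > 0, axis=2).sum())},
                )
            )
        prev = frame
    for cmd in program.commands:
        if cmd.message is None:
            continue
        deadline = cmd.start_s + cmd.duration_s
        actions.append(
            EmulatorAction(
                cmd.start_s,
                "message_show",
                {"text": cmd.message, "deadline_s": deadline},
            )
        )
        for t in range(cmd.start_s, deadline):
            actions.append(
                EmulatorAction(
                    t, "countdown_tick", {"remaining_s": deadline - t}
                )
            )
        if cmd.buzzer:
            actions.append(EmulatorAction(deadline, "buzzer", {}))
    order = {"frame_change": 0, "message_show": 1, "countdown_tick": 2, "buzzer": 3}
    actions.sort(key=lambda a: (a.time_s, order[a.kind]))
    return actions


def events_to_json(events: Iterable[Event]) -> str:
    """JSON export of an expanded event list."""
    payload = [
        {
            "t_on_s": e.t_on_s,
            "t_off_s": e.t_off_s,
            "color": e.color.as_tuple(),
            "source_command": e.source_command,
            "leds": sorted(map(list, e.led_set)),
        }
        for e in events
    ]
    return json.dumps(payload, indent=2)
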