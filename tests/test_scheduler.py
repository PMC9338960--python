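"""Event expansion, 1 Hz timelines, reverse schedules, device emulation."""

import numpy as np
import pytest

from lumiplate import (
    Color,
    Command,
    Well,
    build_timeline,
    compile_program,
    duty_cycle,
    emulate,
    expand,
    parse_program,
    reverse_schedule,
)
from lumiplate.program import Program
from lumiplate.fixtures import random_program
from lumiplate.scheduler import Event, SchedulerError

from conftest import brute_force_frames

HEADER = "target,start,duration,red,green,blue,repeats,interval,message,buzzer"


def _pulse(well="A01", start=0, duration=3, blue=255, repeats=1, interval=0, **kw):
    return Command(
        target=Well(well),
        start_s=start,
        duration_s=duration,
        color=Color(blue=blue),
        repeat_count=repeats,
        repeat_interval_s=interval,
        **kw,
    )


def test_expand_pulse_train(placement_96, matrix):
    prog = Program(commands=[_pulse(repeats=12, interval=300)])
    events = expand(prog, placement_96, matrix)
    assert len(events) == 12
    assert [e.t_on_s for e in events] == list(range(0, 3600, 300))
    assert sum(e.t_off_s - e.t_on_s for e in events) == 36


def test_expand_delayed_train(placement_96, matrix):
    prog = Program(commands=[_pulse(start=1800, repeats=6, interval=300)])
    events = expand(prog, placement_96, matrix)
    assert [e.t_on_s for e in events] == [1800, 2100, 2400, 2700, 3000, 3300]
    assert sum(e.t_off_s - e.t_on_s for e in events) == 18


def test_single_command_single_event(placement_96, matrix):
    events = expand(Program(commands=[_pulse()]), placement_96, matrix)
    assert len(events) == 1
    assert len(events[0].led_set) == 4


def test_event_shorter_than_1s_rejected():
    with pytest.raises(SchedulerError):
        Event(frozenset({(0, 0)}), 5, 5, Color(blue=1), 0)


def test_overlap_takes_channel_max(matrix):
    leds = frozenset({(0, 0)})
    events = [
        Event(leds, 0, 10, Color(blue=100), 0),
        Event(leds, 5, 15, Color(blue=200), 1),
    ]
    tl = build_timeline(events, matrix)
    assert tl.frame_at(7)[0, 0, 2] == 200
    assert tl.frame_at(2)[0, 0, 2] == 100
    assert tl.frame_at(12)[0, 0, 2] == 200


def test_disjoint_events_conserve_led_seconds(matrix):
    events = [
        Event(frozenset({(0, 0), (0, 1)}), 0, 5, Color(blue=10), 0),
        Event(frozenset({(3, 3)}), 10, 12, Color(red=20), 1),
    ]
    tl = build_timeline(events, matrix)
    assert tl.lit_led_seconds() == 2 * 5 + 1 * 2


def test_conflicting_events_never_exceed_sum(placement_96, matrix):
    prog = random_program(11, n_commands=6)
    events = expand(prog, placement_96, matrix)
    tl = build_timeline(events, matrix)
    upper = sum(len(e.led_set) * (e.t_off_s - e.t_on_s) for e in events)
    assert tl.lit_led_seconds() <= upper


@pytest.mark.parametrize("seed", range(20))
def test_timeline_matches_brute_force(seed, placement_96, matrix):
    prog = random_program(
        seed, n_commands=4, max_start_s=120, max_duration_s=10, max_repeats=3,
        max_extra_interval_s=30,
    )
    tl = compile_program(prog, placement_96, matrix)
    oracle = brute_force_frames(prog, placement_96, matrix)
    assert set(tl.frames) == set(oracle)
    for t, grid in oracle.items():
        np.testing.assert_array_equal(tl.frames[t], grid)


def test_order_invariance(placement_96, matrix):
    prog = random_program(5, n_commands=5)
    tl1 = compile_program(prog, placement_96, matrix)
    shuffled = Program(commands=list(reversed(prog.commands)))
    tl2 = compile_program(shuffled, placement_96, matrix)
    assert set(tl1.frames) == set(tl2.frames)
    for t in tl1.frames:
        np.testing.assert_array_equal(tl1.frames[t], tl2.frames[t])


def test_quantization_integer_seconds(placement_96, matrix):
    events = expand(random_program(9, n_commands=5), placement_96, matrix)
    assert all(
        isinstance(e.t_on_s, int) and isinstance(e.t_off_s, int) for e in events
    )
    tl = build_timeline(events, matrix)
    assert all(isinstance(t, int) for t in tl.frames)


def test_duty_cycle_pulse_train(placement_96, matrix):
    # 10-s pulse every 2 min, the high-frequency stimulation scheme
    prog = Program(commands=[_pulse(duration=10, repeats=42, interval=120)])
    tl = compile_program(prog, placement_96, matrix)
    assert duty_cycle(tl, (0, 0), (0, 4920)) == pytest.approx(10 / 120)


def test_duty_cycle_extremes(placement_96, matrix):
    always = compile_program(Program(commands=[_pulse(duration=50)]), placement_96)
    assert duty_cycle(always, (0, 0), (0, 50)) == 1.0
    assert duty_cycle(always, (30, 60), (0, 50)) == 0.0  # LED never addressed


def test_duty_cycle_empty_window(placement_96):
    tl = compile_program(Program(commands=[_pulse()]), placement_96)
    with pytest.raises(SchedulerError):
        duty_cycle(tl, (0, 0), (5, 5))


def test_reverse_schedule_staggered_starts():
    # 12 time points at 2-min resolution, 10-s pulse
    tps = [120 * k for k in range(1, 13)]
    wells = [f"A{k:02d}" for k in range(1, 13)]
    prog = reverse_schedule(tps, _pulse(duration=10), wells)
    assert prog.fixation_horizon_s == 1440
    starts = {c.target.address: c.start_s for c in prog.commands}
    assert starts["A01"] == 1440 - 120
    assert starts["A12"] == 0
    assert all(1440 - starts[w] == tp for w, tp in zip(wells, tps))


def test_reverse_schedule_single_point():
    prog = reverse_schedule([300], _pulse(duration=10), ["B02"])
    (cmd,) = prog.commands
    assert cmd.start_s == 0 and cmd.target == Well("B02")


def test_reverse_schedule_round_trip(placement_96, matrix):
    tps = [60, 180, 420]
    prog = reverse_schedule(tps, _pulse(duration=2), ["A01", "B01", "C01"])
    events = expand(prog, placement_96, matrix)
    recovered = sorted(prog.fixation_horizon_s - e.t_on_s for e in events)
    assert recovered == sorted(tps)


def test_reverse_schedule_errors():
    with pytest.raises(SchedulerError):
        reverse_schedule([100], _pulse(duration=10), ["A01"], horizon_s=50)
    with pytest.raises(SchedulerError):
        reverse_schedule([5], _pulse(duration=10), ["A01"])  # pulse outlasts point


def test_emulate_single_pulse(placement_96, matrix):
    prog = Program(commands=[_pulse(start=4, duration=3)])
    tl = compile_program(prog, placement_96, matrix)
    actions = emulate(tl, prog)
    changes = [a.time_s for a in actions if a.kind == "frame_change"]
    assert changes == [4, 7]  # on and off transitions only


def test_emulate_message_countdown(placement_96, matrix):
    cmd = _pulse(start=60, duration=30, message="add reagent", buzzer=True)
    prog = Program(commands=[cmd])
    tl = compile_program(prog, placement_96, matrix)
    actions = emulate(tl, prog)
    shows = [a for a in actions if a.kind == "message_show"]
    ticks = [a for a in actions if a.kind == "countdown_tick"]
    buzz = [a for a in actions if a.kind == "buzzer"]
    assert len(shows) == 1 and shows[0].time_s == 60
    assert len(ticks) == 30
    assert ticks[0].payload["remaining_s"] == 30
    assert [b.time_s for b in buzz] == [90]


def test_emulate_empty_program(matrix):
    prog = Program()
    tl = compile_program(prog, None, matrix)
    assert emulate(tl, prog) == []
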