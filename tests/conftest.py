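import numpy as np
import pytest
from hypothesis import settings

from lumiplate import MatrixSpec, default_placement, default_registry

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def matrix():
    return MatrixSpec()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def placement_96(registry):
    return default_placement(registry["96-well"])


@pytest.fixture(scope="session")
def placement_6(registry):
    return default_placement(registry["6-well"])


def brute_force_frames(program, placement, matrix):
    """Independent per-second simulator: loops over every second and
    every command, ignoring the event machinery entirely."""
    from lumiplate import resolve_target

    resolved = [
        resolve_target(cmd.target, placement, matrix) for cmd in program.commands
    ]
    frames = {}
    for t in range(program.horizon_s):
        grid = np.zeros((matrix.n_rows, matrix.n_cols, 3), dtype=np.uint8)
        for cmd, leds in zip(program.commands, resolved):
            for k in range(cmd.repeat_count):
                t_on = cmd.start_s + k * cmd.repeat_interval_s
                if t_on <= t < t_on + cmd.duration_s:
                    for r, c in leds:
                        grid[r, c] = np.maximum(
                            grid[r, c], np.array(cmd.color.as_tuple(), dtype=np.uint8)
                        )
        if grid.any():
            frames[t] = grid
    return frames
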