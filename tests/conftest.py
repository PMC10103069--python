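import numpy as np
import pytest

from pseudopupil import synthetic as syn


@pytest.fixture(scope="session")
def sine_trajectory():
    """Smooth 0.5 Hz sinusoidal trajectory, 6 s at 100 Hz (no saccades)."""
    dt = 0.01
    times = np.arange(0.0, 6.0, dt)
    x = 2.0 * np.sin(2 * np.pi * 0.5 * times)
    return syn.TrajectoryGT(times=times, x=x, y=np.zeros_like(x),
                            smooth_x=x, smooth_y=np.zeros_like(x))


@pytest.fixture(scope="session")
def tracked_stack(sine_trajectory):
    """Rendered seven-dot stack plus its ground-truth pixel trace."""
    scene = syn.SceneParams(seed=1)
    stack, px = syn.gen_frames(sine_trajectory, scene)
    return stack, px
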