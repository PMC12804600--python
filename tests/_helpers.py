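import numpy as np


def make_trajectory(x, y, frame_rate=10.0, arena_id="ymaze"):
    """Trajectory from coordinate arrays with a uniform frame clock."""
    from navscope.io import Trajectory
    x = np.asarray(x, dtype=float)
    t = np.arange(len(x)) / frame_rate
    return Trajectory(timestamps=t, x=x, y=np.asarray(y, dtype=float),
                      frame_rate=frame_rate, arena_id=arena_id)
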