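import numpy as np
import pytest

from typescreen.sessions import KeyEvent, RawTypingSession


def make_session(
    presses,
    holds=None,
    coords=None,
    deletes=None,
    subject_id="s1",
    session_id="sess1",
    density=254.0,
    start_time=None,
    distances_mm=None,
):
    """Build a session from press times and per-key hold times."""
    presses = list(presses)
    holds = list(holds) if holds is not None else [100] * len(presses)
    if coords is None and distances_mm is None:
        coords = [(10 * i, 5 * i) for i in range(len(presses))]
    deletes = deletes or [False] * len(presses)
    events = [
        KeyEvent(
            press_time=int(p),
            release_time=int(p + h),
            x=None if coords is None else float(coords[i][0]),
            y=None if coords is None else float(coords[i][1]),
            is_delete=deletes[i],
        )
        for i, (p, h) in enumerate(zip(presses, holds))
    ]
    return RawTypingSession(
        subject_id=subject_id,
        session_id=session_id,
        start_time=int(start_time if start_time is not None else presses[0] - 500),
        events=events,
        screen_density_x=density,
        screen_density_y=density,
        distances_mm=distances_mm,
    )


def random_session(rng, n_keys=12, subject_id="s1", session_id="sess", overlap=False):
    """Random valid session: positive holds, mostly positive flights."""
    holds = rng.integers(40, 280, n_keys)
    flights = rng.integers(30, 900, max(n_keys - 1, 0)).astype(int)
    if overlap and n_keys > 1:
        k = rng.integers(0, n_keys - 1)
        flights[k] = -int(min(holds[k], holds[k + 1]) // 2)
    presses = [1_000_000]
    for i in range(n_keys - 1):
        presses.append(presses[-1] + int(holds[i]) + int(flights[i]))
    coords = [(int(rng.integers(0, 1000)), int(rng.integers(0, 600))) for _ in range(n_keys)]
    return make_session(
        presses, holds=holds, coords=coords,
        subject_id=subject_id, session_id=session_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


#: single-combination grid keeping tree counts small for fast tests
FAST_GRID = {"n_estimators": [25], "max_depth": [None]}
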