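"""Keystroke dynamics variables and their conditional filtering.

For a session of N keys with press/release timestamps ``t_n^p``, ``t_n^r``:

* hold time      ``HT_n = t_n^r - t_n^p``                  (n = 1..N, ms)
* flight time    ``FT_n = t_{n+1}^p - t_n^r``              (n = 1..N-1, ms);
  negative when the next key is pressed before the previous is released
  (two-handed overlap)
* distance       ``D_n``: Euclidean inter-key distance in mm (n = 1..N-1)
* speed          ``SP_n = D_n / FT_n``                     (mm/ms)
* press-flight rate ``PFR_n = HT_n / FT_n``                (dimensionless)

Filtering removes pauses (FT > 3 s), overlap (FT <= 0, which would make the
SP/PFR ratios meaningless) and deliberate long presses (HT > 300 ms by
default).  Removing FT_n cascades to SP_n and PFR_n; removing HT_n cascades
to PFR_n only.  Sessions with fewer than eight keys are invalid, and sessions
whose filtered-FT median sits more than three standard deviations from the
mean of the user's session medians are flagged as outliers (e.g. typing while
walking) and excluded from feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .sessions import RawTypingSession, compute_event_distances

__all__ = [
    "FilterConfig",
    "DynamicsSequences",
    "compute_hold_times",
    "compute_flight_times",
    "compute_distances",
    "compute_speed_and_pfr",
    "compute_dynamics",
    "apply_timing_filters",
    "extract_dynamics",
    "is_valid_session",
    "flag_outlier_sessions",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the conditional filters (units: milliseconds unless noted)."""

    ft_max_ms: float = 3000.0         # pauses: FT above this are removed
    ft_min_exclusive_ms: float = 0.0  # overlap: FT at or below this are removed
    long_press_ms: float = 300.0      # deliberate long-press threshold on HT
    min_keys: int = 8                 # session validity: minimum keys typed
    outlier_sigma: float = 3.0        # per-user session FT-median outlier rule


@dataclass
class DynamicsSequences:
    """Per-session dynamics with filter masks over the raw index space.

    ``ht_raw`` has length N, ``ft_raw`` and ``dist`` length N-1; the boolean
    ``ht_keep``/``ft_keep`` masks record which raw entries survive filtering.
    Filtered views (``ht``, ``ft``, ``sp``, ``pfr``) are derived from the
    masks, which makes filtering idempotent by construction.
    """

    ht_raw: np.ndarray
    ft_raw: np.ndarray
    dist: np.ndarray
    ht_keep: np.ndarray = field(default=None)  # type: ignore[assignment]
    ft_keep: np.ndarray = field(default=None)  # type: ignore[assignment]
    long_press_count: int = 0
    filtered: bool = False

    def __post_init__(self) -> None:
        self.ht_raw = np.asarray(self.ht_raw, dtype=float)
        self.ft_raw = np.asarray(self.ft_raw, dtype=float)
        self.dist = np.asarray(self.dist, dtype=float)
        if len(self.ft_raw) != max(len(self.ht_raw) - 1, 0):
            raise ValueError("ft_raw must have length n_raw - 1")
        if len(self.dist) != len(self.ft_raw):
            raise ValueError("dist must be index-aligned with ft_raw")
        if self.ht_keep is None:
            self.ht_keep = np.ones(len(self.ht_raw), dtype=bool)
        if self.ft_keep is None:
            self.ft_keep = np.ones(len(self.ft_raw), dtype=bool)

    @property
    def n_raw(self) -> int:
        return len(self.ht_raw)

    @property
    def ht(self) -> np.ndarray:
        return self.ht_raw[self.ht_keep]

    @property
    def ft(self) -> np.ndarray:
        return self.ft_raw[self.ft_keep]

    @property
    def sp(self) -> np.ndarray:
        """Speeds over surviving flight times (needs positive FT)."""
        self._check_positive_ft()
        return self.dist[self.ft_keep] / self.ft_raw[self.ft_keep]

    @property
    def pfr(self) -> np.ndarray:
        """Press-flight rates over indices where both HT_n and FT_n survive."""
        self._check_positive_ft()
        keep = self.ft_keep & self.ht_keep[:-1] if self.n_raw > 0 else self.ft_keep
        return self.ht_raw[:-1][keep] / self.ft_raw[keep]

    def _check_positive_ft(self) -> None:
        if not self.filtered and np.any(self.ft_raw[self.ft_keep] <= 0):
            raise ValueError(
                "SP/PFR require strictly positive flight times; apply filters first"
            )


def compute_hold_times(session: RawTypingSession) -> np.ndarray:
    """``HT_n = t_n^r - t_n^p`` for every key of the session (ms)."""
    if session.n_keys == 0:
        raise ValueError(f"session {session.session_id} has no events")
    return np.array(
        [e.release_time - e.press_time for e in session.events], dtype=float
    )


def compute_flight_times(session: RawTypingSession) -> np.ndarray:
    """``FT_n = t_{n+1}^p - t_n^r`` (ms); negative under two-handed overlap."""
    ev = session.events
    return np.array(
        [b.press_time - a.release_time for a, b in zip(ev, ev[1:])], dtype=float
    )


def compute_distances(session: RawTypingSession) -> np.ndarray:
    """Inter-key Euclidean distances in millimetres (length N-1).

    Pixel offsets are scaled by 25.4 / screen density (ppi) per axis; sessions
    captured in privacy mode pass their precomputed distances through.
    """
    return np.asarray(compute_event_distances(session), dtype=float)


def compute_speed_and_pfr(
    ht: Sequence[float], ft: Sequence[float], dist: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """``SP_n = D_n / FT_n`` and ``PFR_n = HT_n / FT_n`` over filtered, aligned inputs.

    ``ht`` may be the full N-length sequence or already trimmed to N-1; entries
    are paired index-wise with the flight to the next key.  All flight times
    must be strictly positive (filter first).
    """
    ht = np.asarray(ht, dtype=float)
    ft = np.asarray(ft, dtype=float)
    dist = np.asarray(dist, dtype=float)
    if np.any(ft <= 0):
        raise ValueError("flight times must be strictly positive (filter first)")
    if len(dist) != len(ft):
        raise ValueError("dist and ft must be index-aligned")
    ht_paired = ht[: len(ft)]
    if len(ht_paired) != len(ft):
        raise ValueError("ht too short to pair with ft")
    return dist / ft, ht_paired / ft


def compute_dynamics(session: RawTypingSession) -> DynamicsSequences:
    """Raw (unfiltered) dynamics sequences of one session."""
    ht = compute_hold_times(session)
    ft = compute_flight_times(session)
    dist = compute_distances(session)
    return DynamicsSequences(ht_raw=ht, ft_raw=ft, dist=dist)


def apply_timing_filters(
    dyn: DynamicsSequences, cfg: FilterConfig | None = None
) -> DynamicsSequences:
    """Apply pause, overlap and long-press filters; idempotent.

    FT entries outside ``(ft_min_exclusive_ms, ft_max_ms]`` are removed
    (cascading to SP and PFR); HT entries above ``long_press_ms`` are removed
    (cascading to PFR only) and counted as long presses.
    """
    cfg = cfg or FilterConfig()
    ht_ok = dyn.ht_keep & (dyn.ht_raw <= cfg.long_press_ms)
    ft_ok = (
        dyn.ft_keep
        & (dyn.ft_raw > cfg.ft_min_exclusive_ms)
        & (dyn.ft_raw <= cfg.ft_max_ms)
    )
    return replace(
        dyn,
        ht_keep=ht_ok,
        ft_keep=ft_ok,
        long_press_count=int(np.sum(~ht_ok)),
        filtered=True,
    )


def extract_dynamics(
    session: RawTypingSession, cfg: FilterConfig | None = None
) -> DynamicsSequences:
    """Compute and filter the dynamics of one session in one call."""
    return apply_timing_filters(compute_dynamics(session), cfg)


def is_valid_session(session: RawTypingSession, min_keys: int = 8) -> bool:
    """A session is valid when at least ``min_keys`` keys were typed."""
    return session.n_keys >= min_keys


def flag_outlier_sessions(
    user_sessions: Sequence[DynamicsSequences], outlier_sigma: float = 3.0
) -> np.ndarray:
    """Per-user outlier mask over sessions by the 3-sigma FT-median rule.

    For one user's sessions, let mu and sigma be the mean and (population)
    standard deviation of the per-session medians of filtered FT.  A session
    is flagged when ``|median - mu| > outlier_sigma * sigma``; its FT-derived
    sequences (FT, SP, PFR) are then excluded from feature extraction.
    Users with fewer than two sessions, degenerate sigma = 0, or sessions with
    empty filtered FT never flag.
    """
    n = len(user_sessions)
    mask = np.zeros(n, dtype=bool)
    if n < 2:
        return mask
    medians = np.full(n, np.nan)
    for i, dyn in enumerate(user_sessions):
        ft = dyn.ft
        if len(ft):
            medians[i] = np.median(ft)
    valid = ~np.isnan(medians)
    if valid.sum() < 2:
        return mask
    mu = np.mean(medians[valid])
    sigma = np.std(medians[valid])
    if sigma == 0:
        return mask
    mask[valid] = np.abs(medians[valid] - mu) > outlier_sigma * sigma
    return mask
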