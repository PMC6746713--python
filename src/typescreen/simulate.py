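"""Synthetic typing-cohort generator.

Real typing logs from depression-screening studies are not publicly
shareable, so this module generates raw key-event streams with the
statistical structure the screening pipeline assumes:

* per-key hold and flight times drawn from log-normal distributions with
  subject-level random effects around group parameters;
* a planted psychomotor effect: the DT group has a longer median hold time
  and more dispersed SP/PFR (slower, more variable typing), matching the
  direction of the group differences the pipeline is meant to detect;
* two-handed overlap (negative flight times), long pauses (> 3 s), deliberate
  long presses (> 300 ms) and delete keys injected at configurable rates;
* key coordinates on a content-free virtual QWERTY-like grid (only inter-key
  distances matter, key identity is never modelled);
* PHQ-9 item responses drawn so compound scores land in each group's range,
  with group means anchored at realistic cohort values;
* session-per-day counts Poisson-distributed around group means.

Everything is reproducible from ``CohortSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .sessions import KeyEvent, RawTypingSession, Subject

__all__ = ["CohortSpec", "generate_cohort", "plant_effect", "cohort_frames"]

MS_PER_DAY = 86_400_000


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of the synthetic cohort (DT first in pairs).

    Defaults encode the emulated study conditions: 11 DT / 14 HC subjects,
    PHQ-9 group means 10.64 / 2.29 (DT scores in [5, 15], HC in [0, 4]),
    55.14 / 66.46 sessions per day, a 40 ms DT hold-time median shift and a
    1.5x DT dispersion multiplier on SP/PFR.  ``days`` defaults to a short
    window so that default cohorts stay desk-scale end to end.
    """

    n_dt: int = 11
    n_hc: int = 14
    days: int = 3
    sessions_per_day_mean: tuple[float, float] = (55.14, 66.46)
    keys_per_session_mean: float = 16.0
    keys_per_session_min: int = 2
    ht_median_ms: tuple[float, float] = (130.0, 90.0)
    ht_log_sd: float = 0.25
    ft_median_ms: float = 350.0
    ft_log_sd: float = 0.35
    subject_log_sd_ht: float = 0.12
    subject_log_sd_ft: float = 0.15
    day_log_sd: float = 0.08
    session_log_sd_ht: float = 0.15
    session_log_sd_ft: float = 0.20
    pfr_dispersion_multiplier: float = 1.5
    p_overlap: float = 0.04
    p_pause: float = 0.03
    p_longpress: float = 0.02
    delete_rate: float = 0.08
    phq9_mean: tuple[float, float] = (10.64, 2.29)
    phq9_sd: tuple[float, float] = (3.47, 1.73)
    phq9_range: tuple[tuple[int, int], tuple[int, int]] = ((5, 15), (0, 4))
    phq9_noise: float = 1.0
    screen_ppi: float = 400.0
    key_pitch_mm: float = 6.0
    grid_cols: int = 10
    grid_rows: int = 4
    start_epoch_ms: int = 1_546_300_800_000  # 2019-01-01 UTC
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_overlap, self.p_pause, self.p_longpress, self.delete_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of [0, 1]: {p}")
        if self.n_dt < 1 or self.n_hc < 1 or self.days < 1:
            raise ValueError("subject and day counts must be >= 1")
        if self.ht_log_sd <= 0 or self.ft_log_sd <= 0:
            raise ValueError("log-sds must be positive")
        if self.keys_per_session_min < 2:
            raise ValueError("keys_per_session_min must be >= 2")
        if self.pfr_dispersion_multiplier < 1.0:
            raise ValueError("dispersion multiplier must be >= 1")
        (dt_lo, dt_hi), (hc_lo, hc_hi) = self.phq9_range
        if not (dt_lo >= 5 and self.phq9_mean[0] >= 5):
            raise ValueError("DT PHQ-9 scores must sit at or above the cutoff of 5")
        if not (0 <= hc_lo <= hc_hi <= 4):
            raise ValueError("HC PHQ-9 scores must sit below the cutoff of 5")


def plant_effect(
    spec: CohortSpec, ht_shift_ms: float, dispersion_multiplier: float = 1.0
) -> CohortSpec:
    """Spec with the DT hold-time median raised by ``ht_shift_ms`` over HC's
    and the DT SP/PFR dispersion scaled by ``dispersion_multiplier``.

    The HC group is untouched; shift 0 with multiplier 1 plants no effect.
    """
    if ht_shift_ms < 0:
        raise ValueError("ht_shift_ms must be >= 0")
    if dispersion_multiplier < 1.0:
        raise ValueError("dispersion_multiplier must be >= 1")
    hc = spec.ht_median_ms[1]
    return replace(
        spec,
        ht_median_ms=(hc + ht_shift_ms, hc),
        pfr_dispersion_multiplier=dispersion_multiplier,
    )


def _draw_phq9_items(
    rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int
) -> list[int]:
    """Item responses whose compound score is a truncated draw around the
    group mean; score mass is spread over random items capped at 3."""
    target = int(np.clip(np.rint(rng.normal(mean, sd)), lo, hi))
    items = np.zeros(9, dtype=int)
    while items.sum() < target:
        open_items = np.flatnonzero(items < 3)
        items[rng.choice(open_items)] += 1
    return items.tolist()


def _lognormal_std_factor(sigma: float) -> float:
    """Standard deviation of a log-normal with unit median and log-sd sigma."""
    return float(np.exp(sigma**2 / 2) * np.sqrt(np.expm1(sigma**2)))


def dispersion_log_factor(sigma_pfr: float, multiplier: float) -> float:
    """Factor c such that scaling the HT/FT log-sds by c scales the
    log-normal PFR standard deviation by ``multiplier``.

    PFR = HT/FT of independent log-normals has log-sd
    ``sigma_pfr = sqrt(sigma_HT^2 + sigma_FT^2)`` and standard deviation
    ``median * g(sigma_pfr)``; c solves ``g(c * sigma_pfr) = m * g(sigma_pfr)``.
    """
    if multiplier == 1.0:
        return 1.0
    from scipy.optimize import brentq

    target = multiplier * _lognormal_std_factor(sigma_pfr)
    return float(
        brentq(lambda c: _lognormal_std_factor(c * sigma_pfr) - target, 1.0, 20.0)
    )


def _generate_session_events(
    rng: np.random.Generator,
    spec: CohortSpec,
    ht_med: float,
    ft_med: float,
    dispersion: float,
    n_keys: int,
    session_start: int,
) -> list[KeyEvent]:
    # `dispersion` scales the key-level log-sds (computed so PFR/SP spread
    # grows linearly with the spec multiplier)
    ht = ht_med * np.exp(spec.ht_log_sd * dispersion * rng.standard_normal(n_keys))
    ht = np.maximum(ht, 10.0)
    # deliberate long presses
    lp_mask = rng.random(n_keys) < spec.p_longpress
    ht[lp_mask] = rng.uniform(320.0, 900.0, lp_mask.sum())

    n_gaps = n_keys - 1
    ft = ft_med * np.exp(spec.ft_log_sd * dispersion * rng.standard_normal(n_gaps))
    ft = np.maximum(ft, 15.0)
    u = rng.random(n_gaps)
    pause_mask = u < spec.p_pause
    overlap_mask = (u >= spec.p_pause) & (u < spec.p_pause + spec.p_overlap)
    ft[pause_mask] = rng.uniform(3100.0, 12000.0, pause_mask.sum())
    for i in np.flatnonzero(overlap_mask):
        cap = 0.8 * min(ht[i], ht[i + 1])
        if cap > 6.0:  # keep press and release sequences strictly increasing
            ft[i] = -rng.uniform(5.0, cap)

    ht_i = np.maximum(np.rint(ht).astype(np.int64), 1)
    ft_i = np.rint(ft).astype(np.int64)
    ft_i[ft_i == 0] = 1

    cols = rng.integers(0, spec.grid_cols, n_keys)
    rows = rng.integers(0, spec.grid_rows, n_keys)
    pitch_px = spec.key_pitch_mm / 25.4 * spec.screen_ppi
    xs = (cols + 0.5) * pitch_px
    ys = (rows + 0.5) * pitch_px
    deletes = rng.random(n_keys) < spec.delete_rate

    events = []
    t_press = session_start + int(rng.integers(200, 800))
    prev_release = None
    for k in range(n_keys):
        release = t_press + int(ht_i[k])
        if prev_release is not None and release <= prev_release:
            release = prev_release + 1  # guard against rounding collisions
        events.append(
            KeyEvent(
                press_time=t_press,
                release_time=release,
                x=float(xs[k]),
                y=float(ys[k]),
                is_delete=bool(deletes[k]),
            )
        )
        prev_release = release
        if k < n_gaps:
            nxt = release + int(ft_i[k])
            t_press = max(nxt, t_press + 1)
    return events


def generate_cohort(spec: CohortSpec) -> list[Subject]:
    """Generate the full cohort: subjects with PHQ-9 items and raw sessions.

    DT subjects come first (ids ``dt00`` ...), then HC (``hc00`` ...); all
    randomness derives from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    subjects: list[Subject] = []
    for group_idx, (prefix, n_subj) in enumerate((("dt", spec.n_dt), ("hc", spec.n_hc))):
        spd_mean = spec.sessions_per_day_mean[group_idx]
        ht_med_group = spec.ht_median_ms[group_idx]
        sigma_pfr = float(np.hypot(spec.ht_log_sd, spec.ft_log_sd))
        dispersion = (
            dispersion_log_factor(sigma_pfr, spec.pfr_dispersion_multiplier)
            if group_idx == 0
            else 1.0
        )
        mean, sd = spec.phq9_mean[group_idx], spec.phq9_sd[group_idx]
        lo, hi = spec.phq9_range[group_idx]
        for j in range(n_subj):
            subject_id = f"{prefix}{j:02d}"
            items = _draw_phq9_items(rng, mean, sd * spec.phq9_noise, lo, hi)
            ht_med = float(
                np.exp(rng.normal(np.log(ht_med_group), spec.subject_log_sd_ht))
            )
            ft_med = float(
                np.exp(rng.normal(np.log(spec.ft_median_ms), spec.subject_log_sd_ft))
            )
            sessions = []
            counter = 0
            for day in range(spec.days):
                n_sessions = rng.poisson(spd_mean)
                day_start = spec.start_epoch_ms + day * MS_PER_DAY
                day_factor = float(np.exp(rng.normal(0.0, spec.day_log_sd)))
                offsets = np.sort(
                    rng.integers(8 * 3_600_000, 23 * 3_600_000, n_sessions)
                )
                for off in offsets:
                    n_keys = max(
                        spec.keys_per_session_min,
                        int(rng.poisson(spec.keys_per_session_mean)),
                    )
                    start = int(day_start + off)
                    # session- and day-level rhythm fluctuation: typing pace
                    # varies with context, posture and time of day
                    sess_ht = ht_med * day_factor * float(
                        np.exp(rng.normal(0.0, spec.session_log_sd_ht))
                    )
                    sess_ft = ft_med * day_factor * float(
                        np.exp(rng.normal(0.0, spec.session_log_sd_ft))
                    )
                    events = _generate_session_events(
                        rng, spec, sess_ht, sess_ft, dispersion, n_keys, start
                    )
                    sessions.append(
                        RawTypingSession(
                            subject_id=subject_id,
                            session_id=f"{subject_id}-s{counter:05d}",
                            start_time=start,
                            app_name="messenger",
                            events=events,
                            screen_density_x=spec.screen_ppi,
                            screen_density_y=spec.screen_ppi,
                        )
                    )
                    counter += 1
            subjects.append(
                Subject(
                    subject_id=subject_id,
                    phq9_items=items,
                    age=float(np.clip(rng.normal(23.7, 3.9), 18, 40)),
                    gender=str(rng.choice(["f", "m"])),
                    education=str(rng.choice(["high-school", "university"], p=[0.7, 0.3])),
                    sessions=sessions,
                )
            )
    return subjects


def cohort_frames(spec: CohortSpec, filter_cfg=None, cutoff: int = 5):
    """Convenience: generate a cohort and return (features, labels, subjects).

    ``features`` is the extracted session feature table; ``labels`` the
    subject label table at the given PHQ-9 cutoff.
    """
    from .features import extract_feature_table
    from .phq9 import label_table

    subjects = generate_cohort(spec)
    all_sessions = [s for subj in subjects for s in subj.sessions]
    features, report = extract_feature_table(all_sessions, filter_cfg)
    labels = label_table(subjects, cutoff=cutoff)
    return features, labels, subjects
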