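"""Peak expiratory flow cleaning, personal-best estimation, zone classification.

Per session, up to three PEF readings (L/min) are reduced to the highest
valid reading after removing gross errors (>1000 L/min). A participant's
personal best is the highest session maximum not exceeding the 95th
percentile of their session maxima (percentile by linear interpolation
between order statistics), which caps isolated effort or entry errors at the
top of the range. Session PEF is then expressed as a percentage of personal
best; values outside [20%, 120%] are excluded as clinically implausible and
the remainder fall into green (>=80%), yellow (50-79%) or red (<50%) zones.

The design is two-pass and non-iterative: personal best is estimated once
from all session maxima, then the plausibility exclusion is applied; an
excluded session never triggers re-estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_PLAUSIBLE_LPM = 1000.0
REL_PCT_MIN, REL_PCT_MAX = 20.0, 120.0


class PEFDomainError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


def session_max_pef(readings) -> float:
    """Highest valid reading of one session; NaN when none remain.

    Readings above 1000 L/min are removed as entry errors; negative readings
    are a domain error (a flow cannot be negative). NaN entries are ignored.
    """
    arr = np.asarray([r for r in readings if r is not None and not np.isnan(r)], dtype=float)
    if (arr < 0).any():
        raise PEFDomainError(f"negative PEF reading in {list(arr)}")
    arr = arr[arr <= MAX_PLAUSIBLE_LPM]
    if arr.size == 0:
        return float("nan")
    return float(arr.max())


def personal_best(session_maxes, percentile: float = 95.0) -> float:
    """Highest session maximum not exceeding the series' 95th percentile.

    The percentile uses linear interpolation between order statistics
    (numpy's default). Because the percentile is at least the series minimum,
    a qualifying value always exists; for a constant series the result is
    that constant.
    """
    arr = np.asarray(list(session_maxes), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise InsufficientDataError("no valid session maxima to estimate personal best")
    cap = np.percentile(arr, percentile)
    return float(arr[arr <= cap].max())


def relative_pef(session_max: float, personal_best_lpm: float) -> tuple[float, str | None]:
    """Session PEF as percent of personal best with zone, or exclusion.

    Returns ``(relative_pct, zone)``; ``zone`` is ``None`` when the value is
    outside the plausible [20, 120] percent band (the exclusion reason is the
    out-of-band value itself).
    """
    if not personal_best_lpm > 0:
        raise PEFDomainError(f"personal best must be positive, got {personal_best_lpm}")
    pct = 100.0 * session_max / personal_best_lpm
    if pct < REL_PCT_MIN or pct > REL_PCT_MAX:
        return pct, None
    if pct >= 80.0:
        zone = "GREEN"
    elif pct >= 50.0:
        zone = "YELLOW"
    else:
        zone = "RED"
    return pct, zone


@dataclass
class PEFProfile:
    participant_id: str
    personal_best_lpm: float
    session_max_series: pd.DataFrame  # session_id, session_max_lpm
    excluded_readings: list[tuple[int, float, str]] = field(default_factory=list)


def pef_profiles(sessions: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full PEF stage over a session table.

    Returns ``(profiles, relative)``:

    * ``profiles`` — one row per participant with any valid PEF data:
      ``participant_id, personal_best_lpm, n_sessions_used, n_excluded``.
    * ``relative`` — one row per session with a valid session maximum:
      ``session_id, participant_id, session_max_lpm, relative_pct, zone``
      (``zone`` NaN when excluded as implausible relative to personal best).

    Sessions with zero valid readings appear in neither frame; downstream
    they carry no state label but still count toward engagement.
    """
    pef = sessions[["session_id", "participant_id", "pef_1", "pef_2", "pef_3"]].copy()
    readings = pef[["pef_1", "pef_2", "pef_3"]].to_numpy(dtype=float)
    if np.nanmin(readings, initial=0.0) < 0:
        raise PEFDomainError("negative PEF reading in session table")
    valid = np.where(readings <= MAX_PLAUSIBLE_LPM, readings, np.nan)
    any_valid = ~np.isnan(valid).all(axis=1)
    session_max = np.full(len(valid), np.nan)
    session_max[any_valid] = np.nanmax(valid[any_valid], axis=1)
    pef["session_max_lpm"] = session_max
    pef = pef.dropna(subset=["session_max_lpm"])

    profiles = []
    rel_frames = []
    for pid, sub in pef.groupby("participant_id", sort=True):
        pb = personal_best(sub["session_max_lpm"])
        pct = 100.0 * sub["session_max_lpm"].to_numpy() / pb
        zone = np.select(
            [pct < REL_PCT_MIN, pct > REL_PCT_MAX, pct >= 80.0, pct >= 50.0],
            [None, None, "GREEN", "YELLOW"],
            default="RED",
        )
        excluded = (pct < REL_PCT_MIN) | (pct > REL_PCT_MAX)
        profiles.append(
            {
                "participant_id": pid,
                "personal_best_lpm": pb,
                "n_sessions_used": int(len(sub)),
                "n_excluded": int(excluded.sum()),
            }
        )
        rel_frames.append(
            pd.DataFrame(
                {
                    "session_id": sub["session_id"].to_numpy(),
                    "participant_id": pid,
                    "session_max_lpm": sub["session_max_lpm"].to_numpy(),
                    "relative_pct": pct,
                    "zone": zone,
                }
            )
        )
    profiles_df = pd.DataFrame(
        profiles, columns=["participant_id", "personal_best_lpm", "n_sessions_used", "n_excluded"]
    )
    relative_df = (
        pd.concat(rel_frames, ignore_index=True)
        if rel_frames
        else pd.DataFrame(
            columns=["session_id", "participant_id", "session_max_lpm", "relative_pct", "zone"]
        )
    )
    return profiles_df, relative_df
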