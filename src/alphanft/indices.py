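"""Relative alpha amplitude, per-session MRAA, and between-session learning indices.

MRAA(i) is the session-i mean over the six training trials of
(trial alpha amplitude / that session's 2-min baseline alpha amplitude).
Three summaries of the 12-session MRAA trajectory quantify learning:

* L1 = MRAA(12) - MRAA(1), the endpoint change;
* L2 = mean over i=2..12 of [MRAA(i) - MRAA(1)], the averaged deviation
  from the first session (divisor fixed at 11);
* L3 = least-squares slope of MRAA(i) on ln(i), the log-session trend.

A subject with a strictly positive index is a responder for that index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SessionSummary",
    "MRAATrajectory",
    "LearningIndexSet",
    "relative_alpha_amplitude",
    "session_mraa",
    "learning_index_l1",
    "learning_index_l2",
    "learning_index_l3",
    "classify_responder",
    "compute_indices",
    "cohort_mraa",
    "cohort_indices",
]


@dataclass
class SessionSummary:
    session_number: int
    baseline_alpha_uv: float
    trial_alpha_uv: list[float]
    mraa: float


@dataclass
class MRAATrajectory:
    """Ordered per-session MRAA values of one subject.

    Sessions invalidated upstream (all trials rejected) appear as NaN.
    """

    subject_id: str
    mraa_by_session: np.ndarray

    def __post_init__(self) -> None:
        self.mraa_by_session = np.asarray(self.mraa_by_session, dtype=float)

    @property
    def n_sessions(self) -> int:
        return len(self.mraa_by_session)


@dataclass
class LearningIndexSet:
    L1: float
    L2: float
    L3: float

    @property
    def responder_L1(self) -> bool:
        return classify_responder(self.L1)

    @property
    def responder_L2(self) -> bool:
        return classify_responder(self.L2)

    @property
    def responder_L3(self) -> bool:
        return classify_responder(self.L3)


def relative_alpha_amplitude(trial_alpha_uv: float, baseline_alpha_uv: float) -> float:
    """Trial-mean alpha amplitude divided by the session baseline alpha amplitude."""
    if not baseline_alpha_uv > 0:
        raise ValueError("baseline alpha amplitude must be positive")
    return trial_alpha_uv / baseline_alpha_uv


def session_mraa(relative_amplitudes) -> float:
    """Mean relative alpha amplitude over the session's valid trials.

    Trials excluded by the artifact rule simply do not appear; with no valid
    trial the session is missing (NaN).
    """
    vals = [v for v in relative_amplitudes if np.isfinite(v)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def learning_index_l1(traj: MRAATrajectory) -> float:
    """Endpoint change: MRAA(last) - MRAA(1)."""
    first, last = traj.mraa_by_session[0], traj.mraa_by_session[-1]
    if not (np.isfinite(first) and np.isfinite(last)):
        raise ValueError("L1 requires the first and last sessions")
    return float(last - first)


def learning_index_l2(traj: MRAATrajectory) -> float:
    """Averaged deviation from session 1 over sessions 2..k, divisor k-1.

    The divisor is fixed by definition, so a missing session invalidates L2
    (no imputation).
    """
    m = traj.mraa_by_session
    if not np.all(np.isfinite(m)):
        raise ValueError("L2 requires all sessions (fixed divisor)")
    return float(np.sum(m[1:] - m[0]) / (len(m) - 1))


def learning_index_l3(traj: MRAATrajectory) -> float:
    """Least-squares slope of MRAA(i) on ln(i) over the available sessions."""
    m = traj.mraa_by_session
    sessions = np.arange(1, len(m) + 1, dtype=float)
    ok = np.isfinite(m)
    if ok.sum() < 3:
        raise ValueError("L3 requires at least 3 sessions")
    res = stats.linregress(np.log(sessions[ok]), m[ok])
    return float(res.slope)


def classify_responder(index_value: float) -> bool:
    """Responder iff the learning index is strictly positive."""
    if not math.isfinite(index_value):
        raise ValueError("learning index must be finite")
    return index_value > 0


def compute_indices(traj: MRAATrajectory) -> LearningIndexSet:
    return LearningIndexSet(
        L1=learning_index_l1(traj),
        L2=learning_index_l2(traj),
        L3=learning_index_l3(traj),
    )


# ---------------------------------------------------------------------------
# tidy-table entry points
# ---------------------------------------------------------------------------

def cohort_mraa(trial_table: pd.DataFrame,
                baseline_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject-per-session MRAA from tidy alpha-amplitude tables.

    ``trial_table`` columns: subject, session, trial, band, amplitude_uv
    (band == 'alpha' rows are used); ``baseline_table``: subject, session,
    band, amplitude_uv.  Returns a wide subject x session MRAA matrix.
    """
    tr = trial_table[trial_table["band"] == "alpha"]
    ba = baseline_table[baseline_table["band"] == "alpha"]
    base = ba.set_index(["subject", "session"])["amplitude_uv"]
    rows = {}
    for (subj, sess), grp in tr.groupby(["subject", "session"]):
        b = base.loc[(subj, sess)]
        ratios = [relative_alpha_amplitude(v, b) for v in grp["amplitude_uv"]]
        rows.setdefault(subj, {})[sess] = session_mraa(ratios)
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out = out[sorted(out.columns)]
    out.index.name = "subject"
    out.columns = [f"MRAA_{s}" for s in out.columns]
    return out


def cohort_indices(mraa_wide: pd.DataFrame) -> pd.DataFrame:
    """L1/L2/L3 and responder flags for every subject of a wide MRAA matrix."""
    rows = []
    for subj, row in mraa_wide.iterrows():
        traj = MRAATrajectory(subj, row.to_numpy())
        idx = compute_indices(traj)
        rows.append({
            "subject": subj,
            "L1": idx.L1, "L2": idx.L2, "L3": idx.L3,
            "responder_L1": idx.responder_L1,
            "responder_L2": idx.responder_L2,
            "responder_L3": idx.responder_L3,
        })
    return pd.DataFrame(rows).set_index("subject")
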