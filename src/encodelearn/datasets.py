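"""Published group-level sensitivity data for the Kanji discrimination study.

These are the printed group means (and SDs) of same-different sensitivity
d' per encoding duration for the four evaluation sessions (27 trained
participants; session 1 = no training, 4 = low, 7 = medium, 10 = high
training) and the generalization session with novel Kanji exemplars
(16 participants).  They are the direct inputs to the encoding-curve fits
and make the headline fitted parameters reproducible without trial-level
data.

The 150 ms row of the published per-session table is printed as "250" in
the source table; the design contains no 250 ms duration and the value is
stored under 150 ms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trial_data import EVALUATION_DURATIONS_MS

__all__ = [
    "N_PARTICIPANTS",
    "N_GENERALIZATION",
    "evaluation_means",
    "evaluation_sds",
    "generalization_means",
    "group_mean_table",
]

N_PARTICIPANTS = 27
N_GENERALIZATION = 16

_DURATIONS = list(EVALUATION_DURATIONS_MS)

# session -> mean d' per duration (17 ... 1000 ms)
_MEANS = {
    1:  [0.169, 0.581, 0.860, 1.529, 1.884, 2.364, 2.820, 2.805],
    4:  [0.618, 1.485, 2.015, 2.406, 2.936, 3.187, 3.293, 3.368],
    7:  [0.694, 1.741, 2.388, 2.873, 3.166, 3.589, 3.379, 3.520],
    10: [0.813, 1.953, 2.446, 2.889, 3.373, 3.599, 3.579, 3.491],
    11: [0.54, 1.75, 2.35, 2.90, 2.94, 3.04, 3.45, 3.66],
}

_SDS = {
    1:  [0.303, 0.511, 0.501, 0.709, 0.737, 0.634, 0.685, 0.647],
    4:  [0.417, 0.783, 0.698, 0.640, 0.756, 0.715, 0.569, 0.543],
    7:  [0.471, 0.762, 0.685, 0.666, 0.518, 0.535, 0.364, 0.472],
    10: [0.576, 0.874, 0.648, 0.584, 0.529, 0.574, 0.494, 0.467],
    11: [0.58, 0.77, 1.05, 0.72, 0.65, 0.53, 0.44, 0.55],
}


def evaluation_means(session: int) -> pd.Series:
    """Published mean d' per duration for one session (1, 4, 7, 10 or 11)."""
    if session not in _MEANS:
        raise KeyError(f"no published means for session {session}")
    return pd.Series(_MEANS[session], index=np.array(_DURATIONS, float),
                     name=f"session_{session}").rename_axis("encoding_duration_ms")


def evaluation_sds(session: int) -> pd.Series:
    """Published SD of d' per duration for one session."""
    if session not in _SDS:
        raise KeyError(f"no published SDs for session {session}")
    return pd.Series(_SDS[session], index=np.array(_DURATIONS, float),
                     name=f"session_{session}").rename_axis("encoding_duration_ms")


def generalization_means() -> pd.Series:
    """Published mean d' per duration for the generalization session."""
    return evaluation_means(11)


def group_mean_table() -> pd.DataFrame:
    """All published session means, durations as rows, sessions as columns."""
    frame = pd.DataFrame({s: _MEANS[s] for s in sorted(_MEANS)},
                         index=np.array(_DURATIONS, float))
    frame.index.name = "encoding_duration_ms"
    frame.columns.name = "session_index"
    return frame
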