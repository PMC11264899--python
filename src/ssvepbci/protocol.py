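"""Session scheduling and the offline feedback loop.

A session has two instructed baseline phases (30 attend-Gabor trials, then
30 attend-Face trials) used to train the participant-specific decoder, and a
feedback phase of 3 epochs x 50 trials in which each of 10 faces per epoch
appears in a run of 5 consecutive trials and the decoder's calibrated Gabor
probability is fed back after every trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    ATTEND_FACE,
    ATTEND_GABOR,
    BASELINE1,
    BASELINE2,
    FEEDBACK,
    EEGRecording,
)
from .preprocess import epoch as cut_epochs

N_BASELINE_TRIALS = 30
N_FEEDBACK_EPOCHS = 3
N_FACES_PER_EPOCH = 10
N_EXPOSURES = 5
N_FEEDBACK_TRIALS = N_FEEDBACK_EPOCHS * N_FACES_PER_EPOCH * N_EXPOSURES  # 150

#: 30 affective distractors: 15 actors x {sad, angry}
FACE_POOL = tuple(
    f"actor{a:02d}_{emotion}" for a in range(1, 16) for emotion in ("sad", "angry")
)


@dataclass(frozen=True)
class ScheduledTrial:
    trial_index: int
    phase: str
    condition: str
    face_id: str
    epoch_number: int  # 0 for baselines, 1..3 for feedback
    exposure_count: int  # 1..5 within a feedback run; 1 for baselines


@dataclass
class SessionSchedule:
    """Ordered trial list for one session."""

    trials: list[ScheduledTrial]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def phase_trials(self, phase: str) -> list[ScheduledTrial]:
        return [t for t in self.trials if t.phase == phase]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.trials])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SessionSchedule":
        trials = [
            ScheduledTrial(
                trial_index=int(r.trial_index),
                phase=str(r.phase),
                condition=str(r.condition),
                face_id=str(r.face_id),
                epoch_number=int(r.epoch_number),
                exposure_count=int(r.exposure_count),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(trials=trials)


def build_schedule(seed: int, include_feedback: bool = True) -> SessionSchedule:
    """Build a session schedule.

    Face display order is randomly permuted per phase under ``seed``; each
    feedback epoch draws 10 of the 30 faces without replacement and shows
    each for 5 consecutive trials (exposure counts 1..5).
    """
    rng = np.random.default_rng(seed)
    trials: list[ScheduledTrial] = []
    idx = 0

    for phase, condition in ((BASELINE1, ATTEND_GABOR), (BASELINE2, ATTEND_FACE)):
        order = rng.permutation(len(FACE_POOL))[:N_BASELINE_TRIALS]
        for j in order:
            trials.append(
                ScheduledTrial(
                    trial_index=idx,
                    phase=phase,
                    condition=condition,
                    face_id=FACE_POOL[j],
                    epoch_number=0,
                    exposure_count=1,
                )
            )
            idx += 1

    if include_feedback:
        for ep in range(1, N_FEEDBACK_EPOCHS + 1):
            chosen = rng.choice(len(FACE_POOL), size=N_FACES_PER_EPOCH, replace=False)
            for j in chosen:
                for exposure in range(1, N_EXPOSURES + 1):
                    trials.append(
                        ScheduledTrial(
                            trial_index=idx,
                            phase=FEEDBACK,
                            condition=FEEDBACK,
                            face_id=FACE_POOL[j],
                            epoch_number=ep,
                            exposure_count=exposure,
                        )
                    )
                    idx += 1

    return SessionSchedule(trials=trials, seed=seed)


def run_offline_feedback(rec: EEGRecording, model, schedule: SessionSchedule) -> pd.DataFrame:
    """Score every feedback trial of a recording with a calibrated decoder.

    Each score uses only that trial's own epoch.  Returns one row per
    feedback trial with columns ``trial_index, epoch_number, face_id,
    exposure_count, probability``.
    """
    feedback_trials = schedule.phase_trials(FEEDBACK)
    marker_map = {t: o for o, t in rec.markers}
    missing = [t.trial_index for t in feedback_trials if t.trial_index not in marker_map]
    if missing:
        raise ValueError(f"recording has no marker for feedback trial(s) {missing}")

    duration = model.config_duration()
    epochs = {
        e.trial_index: e
        for e in cut_epochs(rec, duration=duration)
        if e.trial_index in marker_map
    }
    rows = []
    for t in feedback_trials:
        score = model.gabor_probability(epochs[t.trial_index])
        rows.append(
            {
                "trial_index": t.trial_index,
                "epoch_number": t.epoch_number,
                "face_id": t.face_id,
                "exposure_count": t.exposure_count,
                "probability": score.probability,
            }
        )
    return pd.DataFrame(rows)


def summarize_feedback(
    scores: pd.DataFrame,
    participant_col: str | None = None,
    decimals: int | None = 2,
) -> pd.DataFrame:
    """Summarize feedback-phase Gabor probabilities per participant.

    Returns, per participant: the grand mean, the mean per exposure count
    1..5, and the mean over the first vs second half of the feedback phase
    (trials 1-75 vs 76-150 in presentation order).  Values are rounded to
    two decimals for reporting (``decimals=None`` keeps full precision); a
    score > 0.50 means the Gabor "won".
    """
    if scores.empty:
        raise ValueError("no feedback scores to summarize")
    if participant_col is None:
        scores = scores.assign(participant=1)
        participant_col = "participant"

    rows = []
    for pid, grp in scores.groupby(participant_col, sort=True):
        grp = grp.sort_values("trial_index")
        n = len(grp)
        half = n // 2
        row = {"participant": pid, "average": grp["probability"].mean()}
        for k in range(1, N_EXPOSURES + 1):
            row[f"exposure_{k}"] = grp.loc[grp["exposure_count"] == k, "probability"].mean()
        row["first_half"] = grp["probability"].iloc[:half].mean()
        row["second_half"] = grp["probability"].iloc[half:].mean()
        rows.append(row)
    out = pd.DataFrame(rows).set_index("participant")
    return out if decimals is None else out.round(decimals)
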