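"""Evaluation statistics for the attention-training protocol.

Covers the four analyses used to judge the decoder and the protocol:

* **Split-half reliability** — Guttman's lambda-4 on even- vs odd-trial
  aggregate feedback scores, the internal-consistency check that the
  probability feedback is stable enough to be meaningful to a participant.
* **Replication rule** — a +/-10% relative band around a reference
  cross-validated accuracy; an independent sample "replicates" when its
  accuracy falls inside the band.
* **Validation contrast** — paired t-test with Cohen's dz = t/sqrt(n) on
  per-participant mean probabilities between the two instructed baselines.
* **Feedback-phase effects** — 2 (Time: first/second half) x 5 (Trial:
  exposures 1-5) repeated-measures ANOVA with partial eta squared, plus
  Pearson correlations between mean Gabor probability and acceptability
  questionnaire items.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ReliabilityReport:
    phase: str
    guttman_coefficient: float
    n_trials_odd: int
    n_trials_even: int

    def __post_init__(self) -> None:
        if self.guttman_coefficient > 1 + 1e-12:
            raise ValueError("Guttman coefficient cannot exceed 1")
        if abs(self.n_trials_odd - self.n_trials_even) > 1:
            raise ValueError("odd/even trial counts must differ by at most 1")


@dataclass
class ReplicationDecision:
    reference_accuracy: float
    tolerance: float
    interval: tuple[float, float]
    observed_accuracy: float
    replicated: bool


@dataclass
class ReplicationInterval:
    """Relative acceptance band ``[ref*(1-tol), ref*(1+tol)]``."""

    reference: float
    tolerance: float

    def __post_init__(self) -> None:
        if not 0 < self.reference <= 1:
            raise ValueError("reference accuracy must lie in (0, 1]")
        if not 0 <= self.tolerance < 1:
            raise ValueError("tolerance must lie in [0, 1)")

    @property
    def lo(self) -> float:
        return self.reference * (1 - self.tolerance)

    @property
    def hi(self) -> float:
        return self.reference * (1 + self.tolerance)

    def check(self, observed: float) -> ReplicationDecision:
        return ReplicationDecision(
            reference_accuracy=self.reference,
            tolerance=self.tolerance,
            interval=(self.lo, self.hi),
            observed_accuracy=observed,
            replicated=bool(self.lo <= observed <= self.hi),
        )


def replication_interval(reference: float, tolerance: float = 0.10) -> ReplicationInterval:
    """Build the +/-``tolerance`` relative acceptance band around ``reference``."""
    return ReplicationInterval(reference=reference, tolerance=tolerance)


@dataclass
class EffectReport:
    """A single inferential result (t, F or r), with its effect size."""

    name: str
    t: float | None = None
    df: float | None = None
    p: float | None = None
    d: float | None = None
    F: float | None = None
    df1: float | None = None
    df2: float | None = None
    eta_p_sq: float | None = None
    r: float | None = None
    n: int | None = None

    def rounded(self, decimals: int = 3) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            out[k] = round(v, decimals) if isinstance(v, float) else v
        return out


# ---------------------------------------------------------------------------
# Guttman split-half reliability
# ---------------------------------------------------------------------------

def guttman_split_half(
    scores: pd.DataFrame,
    unit_col: str = "participant",
    order_col: str = "trial_index",
    score_col: str = "probability",
    phase: str = "feedback",
    aggregate: str = "mean",
) -> ReliabilityReport:
    """Even-odd split-half reliability (Guttman's lambda-4).

    Trials are split by presentation order within each unit (odd positions
    1, 3, 5, ... vs even positions 2, 4, 6, ...); each unit's odd-trial and
    even-trial scores are aggregated (mean by default) and

    ``lambda4 = 2 * (1 - (V_odd + V_even) / V_total)``

    where the variances are taken across units and ``V_total`` is the
    variance of the summed half-scores.  Requires at least 4 trials per unit
    and nonzero total variance.
    """
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    odd_scores, even_scores = [], []
    n_odd = n_even = 0
    for _, grp in scores.groupby(unit_col, sort=True):
        vals = grp.sort_values(order_col)[score_col].to_numpy()
        if len(vals) < 4:
            raise ValueError("split-half reliability needs >= 4 trials per unit")
        odd, even = vals[0::2], vals[1::2]  # positions 1,3,.. and 2,4,.. (1-based)
        n_odd, n_even = len(odd), len(even)
        agg = np.mean if aggregate == "mean" else np.sum
        odd_scores.append(agg(odd))
        even_scores.append(agg(even))
    odd_scores = np.array(odd_scores)
    even_scores = np.array(even_scores)
    if len(odd_scores) < 2:
        raise ValueError("need >= 2 units to take variances across units")
    v_odd = odd_scores.var(ddof=1)
    v_even = even_scores.var(ddof=1)
    v_total = (odd_scores + even_scores).var(ddof=1)
    if v_total == 0:
        raise ValueError("zero total variance: split-half coefficient undefined")
    lam4 = 2.0 * (1.0 - (v_odd + v_even) / v_total)
    return ReliabilityReport(
        phase=phase,
        guttman_coefficient=float(lam4),
        n_trials_odd=n_odd,
        n_trials_even=n_even,
    )


# ---------------------------------------------------------------------------
# Paired contrast
# ---------------------------------------------------------------------------

def paired_t(a, b, name: str = "paired contrast") -> EffectReport:
    """Two-sided paired t-test with Cohen's dz = t / sqrt(n)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    n = len(a)
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    diff = a - b
    if diff.std(ddof=1) == 0:
        # degenerate: identical pairwise shift; t is 0 (no shift) or unbounded
        t = 0.0 if diff.mean() == 0 else np.inf * np.sign(diff.mean())
        p = 1.0 if diff.mean() == 0 else 0.0
    else:
        t, p = sps.ttest_rel(a, b)
    return EffectReport(
        name=name, t=float(t), df=float(n - 1), p=float(p),
        d=float(t / np.sqrt(n)), n=n,
    )


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """``eta_p^2 = F*df1 / (F*df1 + df2)``."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("F must be >= 0 and dfs positive")
    return float(F * df1 / (F * df1 + df2))


# ---------------------------------------------------------------------------
# 2 x 5 repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova_2x5(cells: pd.DataFrame) -> dict[str, EffectReport]:
    """Within-subject ANOVA on a complete Time(2) x Trial(5) cell table.

    ``cells`` is long-format with columns ``participant``, ``time`` (2
    levels), ``trial`` (5 levels) and ``score``: one mean per cell per
    participant.  Classical univariate decomposition, no sphericity
    correction; returns reports for Time, Trial and Time x Trial with
    partial eta squared for each.
    """
    from statsmodels.stats.anova import AnovaRM

    required = {"participant", "time", "trial", "score"}
    if not required.issubset(cells.columns):
        raise ValueError(f"need columns {sorted(required)}")
    counts = cells.groupby(["participant"]).size()
    n_time = cells["time"].nunique()
    n_trial = cells["trial"].nunique()
    if n_time != 2 or n_trial != 5 or (counts != 10).any():
        raise ValueError("each participant needs a complete 2 x 5 cell table")

    res = AnovaRM(
        cells, depvar="score", subject="participant", within=["time", "trial"]
    ).fit()
    tab = res.anova_table  # index: time, trial, time:trial
    out = {}
    for key, label in (("time", "Time"), ("trial", "Trial"), ("time:trial", "Time x Trial")):
        F = float(tab.loc[key, "F Value"])
        df1 = float(tab.loc[key, "Num DF"])
        df2 = float(tab.loc[key, "Den DF"])
        out[label] = EffectReport(
            name=label, F=F, df1=df1, df2=df2,
            p=float(tab.loc[key, "Pr > F"]),
            eta_p_sq=partial_eta_squared(F, df1, df2),
        )
    return out


# ---------------------------------------------------------------------------
# Acceptability correlations
# ---------------------------------------------------------------------------

def acceptability_correlations(
    avg_probabilities: pd.Series | dict,
    questionnaire: pd.DataFrame,
) -> dict[str, EffectReport]:
    """Pearson r between mean Gabor probability and each questionnaire item.

    ``questionnaire`` is participants x items (1-5 Likert responses),
    indexed by participant; participants are matched on the index.  An item
    (or probability vector) with zero variance yields an EffectReport with
    ``r=None`` flagging the undefined correlation.
    """
    probs = pd.Series(avg_probabilities).astype(float)
    common = probs.index.intersection(questionnaire.index)
    if len(common) < 3:
        raise ValueError("need >= 3 matched participants")
    probs = probs.loc[common]
    out = {}
    for item in questionnaire.columns:
        y = questionnaire.loc[common, item].astype(float)
        if probs.std(ddof=0) == 0 or y.std(ddof=0) == 0:
            out[item] = EffectReport(name=item, r=None, p=None, n=len(common))
            continue
        r, p = sps.pearsonr(probs.to_numpy(), y.to_numpy())
        out[item] = EffectReport(name=item, r=float(r), p=float(p), n=len(common))
    return out
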