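"""Leaderboard-style analyses over many scored submissions.

Includes submission ranking, the within-team variance decomposition (how much
of the spread in F-scores is parameter tuning within teams rather than
differences between methods), and the training-fraction resampling experiment
showing that a positive F_train − F_test gap arises as a small-testing-set
artifact even without any fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import SVRecord
from .scoring import ScoreReport, match_calls

__all__ = [
    "SubmissionScore",
    "rank_submissions",
    "within_team_variance",
    "overfitting_resample",
]


@dataclass(frozen=True)
class SubmissionScore:
    """F-scores of one submission on the train/test/combined truth subsets."""

    team_id: str
    submission_index: int
    f_train: float
    f_test: float
    f_all: float
    precision_all: float = 0.0

    def __post_init__(self) -> None:
        for name in ("f_train", "f_test", "f_all", "precision_all"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")


def rank_submissions(scores: Sequence[SubmissionScore]) -> pd.DataFrame:
    """Leaderboard: descending overall F-score, ties by precision then team id."""
    if not scores:
        raise ValueError("cannot rank an empty submission list")
    rows = sorted(
        scores,
        key=lambda s: (-s.f_all, -s.precision_all, s.team_id, s.submission_index),
    )
    return pd.DataFrame([
        {
            "rank": i + 1,
            "team_id": s.team_id,
            "submission_index": s.submission_index,
            "f_all": s.f_all,
            "f_train": s.f_train,
            "f_test": s.f_test,
            "precision_all": s.precision_all,
        }
        for i, s in enumerate(rows)
    ])


def within_team_variance(scores: Sequence[SubmissionScore]) -> float:
    """Within-team sum of squares of F-scores as a percentage of the total.

    Quantifies how much of the overall F-score variability is submissions of
    the same team (parameter tuning) rather than differences between teams.
    Returns NaN when the total sum of squares is zero.
    """
    if len(scores) < 2:
        raise ValueError("within-team variance requires at least 2 submissions")
    values = np.array([s.f_all for s in scores], dtype=float)
    total_ss = float(((values - values.mean()) ** 2).sum())
    if total_ss == 0:
        return float("nan")
    within_ss = 0.0
    teams = sorted({s.team_id for s in scores})
    for team in teams:
        team_vals = np.array([s.f_all for s in scores if s.team_id == team])
        within_ss += float(((team_vals - team_vals.mean()) ** 2).sum())
    return 100.0 * within_ss / total_ss


def _subset_f_score(n_tp: int, n_fn: int, n_fp: int) -> float:
    return ScoreReport.from_counts(n_tp, n_fp, n_fn).f_score


def overfitting_resample(
    truth: Sequence[SVRecord],
    submissions: Sequence[Sequence[SVRecord]],
    totals: Sequence[int] = tuple(range(100, 1001, 100)),
    fracs: Sequence[float] = tuple(np.round(np.arange(0.80, 0.951, 0.01), 2)),
    reps: int = 100,
    seed: int = 0,
    f: float = 100.0,
) -> pd.DataFrame:
    """Median F_train − F_test over resampled {mutation total, training %} grids.

    Each submission is matched against the full truth set once; every
    replicate then draws a truth subset of the given size, splits it into
    train/test at the given fraction, and scores the submission on each side
    (TPs and FNs partition by subset membership; the submission's false
    positives are shared by both sides, since nothing ties a spurious call to
    either).  The per-submission median ΔF over replicates is taken, then the
    median across submissions (column ``median_delta_f``).  Submissions that
    exactly reproduce the truth have ΔF = 0 everywhere; imperfect ones show a
    positive gap growing with the training fraction — the small-testing-set
    artifact this analysis quantifies.
    """
    truth = list(truth)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if max(totals) > len(truth):
        raise ValueError(
            f"mutation total {max(totals)} exceeds the truth set size {len(truth)}"
        )
    # one matching per submission against the full truth set
    matched_mask = []
    n_fp = []
    for calls in submissions:
        match = match_calls(calls, truth, scheme="closeness", f=f)
        matched_ids = {kid for kid, status in match.known_status.items() if status == "TP"}
        matched_mask.append(np.array([rec.id in matched_ids for rec in truth]))
        n_fp.append(sum(1 for status in match.called_status.values() if status == "FP"))

    rng = np.random.default_rng(seed)
    rows = []
    for total in totals:
        for frac in fracs:
            n_train = int(round(frac * total))
            per_sub: list[list[float]] = [[] for _ in submissions]
            for _rep in range(reps):
                idx = rng.choice(len(truth), size=total, replace=False)
                train_idx, test_idx = idx[:n_train], idx[n_train:]
                for s in range(len(submissions)):
                    tp_train = int(matched_mask[s][train_idx].sum())
                    tp_test = int(matched_mask[s][test_idx].sum())
                    f_train = _subset_f_score(tp_train, len(train_idx) - tp_train, n_fp[s])
                    f_test = _subset_f_score(tp_test, len(test_idx) - tp_test, n_fp[s])
                    per_sub[s].append(f_train - f_test)
            medians = [float(np.median(deltas)) for deltas in per_sub]
            rows.append({
                "total": int(total),
                "train_frac": float(frac),
                "median_delta_f": float(np.median(medians)),
            })
    return pd.DataFrame(rows)
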