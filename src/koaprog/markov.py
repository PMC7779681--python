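"""Markov model of KL-grade stage transitions.

Disease stages are the five KL grades; a patient's grade at the next
annual visit is modelled as depending only on the current grade.  The
model counts observed one-visit transitions within each patient and
estimates the row-stochastic transition matrix by maximum likelihood
(optionally Laplace-smoothed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .transition import N_GRADES, TransitionMatrix


@dataclass
class TransitionCounts:
    """Observed one-visit transition counts between KL grades."""

    counts: np.ndarray  # 5x5 integer matrix

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_GRADES, N_GRADES):
            raise ValueError("counts must be 5x5")
        if (self.counts < 0).any():
            raise ValueError("negative transition counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "TransitionCounts") -> "TransitionCounts":
        return TransitionCounts(self.counts + other.counts)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"counts": self.counts.tolist(), "total": self.total}, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def count_transitions(cohort: Cohort) -> TransitionCounts:
    """Count (KL(t), KL(t+1)) pairs over consecutive visits per patient.

    Pairs where either endpoint's grade is missing are skipped; a
    missing intermediate visit breaks the pair rather than bridging two
    non-adjacent visits.
    """
    df = cohort.data.sort_values(["patient_id", "visit"], kind="stable")
    kl = df["kl"].to_numpy(dtype=float)
    pid = df["patient_id"].to_numpy()
    counts = np.zeros((N_GRADES, N_GRADES), dtype=np.int64)
    if len(df) >= 2:
        same = pid[1:] == pid[:-1]
        src, dst = kl[:-1], kl[1:]
        ok = same & ~np.isnan(src) & ~np.isnan(dst)
        np.add.at(counts, (src[ok].astype(int), dst[ok].astype(int)), 1)
    return TransitionCounts(counts)


def estimate_transition_matrix(
    counts: TransitionCounts, smoothing: float = 0.0
) -> TransitionMatrix:
    """Row-wise MLE: (count + smoothing) / (row total + 5 * smoothing).

    An all-zero row with zero smoothing yields the identity row (the
    grade is treated as self-maintaining in the absence of evidence).
    """
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    c = counts.counts.astype(float) + smoothing
    totals = c.sum(axis=1)
    probs = np.eye(N_GRADES)
    nonzero = totals > 0
    probs[nonzero] = c[nonzero] / totals[nonzero, None]
    return TransitionMatrix(probs)


def stationary_check(
    tm: TransitionMatrix,
    horizon: int,
    initial: np.ndarray | None = None,
) -> pd.DataFrame:
    """Propagate an occupancy distribution ``horizon`` steps through ``tm``.

    Returns one row per step (step 0 = the initial distribution); each
    row is verified to sum to 1.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    occ = np.full(N_GRADES, 1.0 / N_GRADES) if initial is None else np.asarray(initial, float)
    rows = [occ]
    for _ in range(horizon):
        occ = occ @ tm.probs
        rows.append(occ)
    out = pd.DataFrame(rows, columns=[f"kl{g}" for g in range(N_GRADES)])
    sums = out.sum(axis=1).to_numpy()
    if not np.allclose(sums, 1.0, atol=1e-12, rtol=0):
        raise AssertionError("occupancy mass not conserved")
    out.insert(0, "step", np.arange(horizon + 1))
    return out


class MarkovStageModel:
    """KL stage-transition model for a longitudinal cohort."""

    def __init__(self, cohort: Cohort, smoothing: float = 0.0):
        self.cohort = cohort
        self.smoothing = smoothing

    def fit(self) -> "MarkovStageResults":
        counts = count_transitions(self.cohort)
        tm = estimate_transition_matrix(counts, self.smoothing)
        return MarkovStageResults(self, counts, tm)


class MarkovStageResults:
    def __init__(self, model: MarkovStageModel, counts: TransitionCounts, tm: TransitionMatrix):
        self.model = model
        self.counts = counts
        self.transition_matrix = tm

    def occupancy(self, horizon: int, initial: np.ndarray | None = None) -> pd.DataFrame:
        return stationary_check(self.transition_matrix, horizon, initial)

    def standard_errors(self) -> np.ndarray:
        """Binomial SEs of the MLE entries, row-conditional."""
        totals = self.counts.counts.sum(axis=1).astype(float)
        p = self.transition_matrix.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(p * (1 - p) / totals[:, None])
        se[totals == 0] = np.nan
        return se

    def summary(self) -> str:
        lines = [
            "Markov KL stage-transition model",
            f"  transitions observed: {self.counts.total}",
            f"  smoothing (pseudo-count): {self.model.smoothing}",
            "  estimated transition matrix P(row -> col):",
        ]
        header = "        " + "".join(f"KL{j:>7}" for j in range(N_GRADES))
        lines.append(header)
        for i in range(N_GRADES):
            row = "".join(f"{v:9.4f}" for v in self.transition_matrix.probs[i])
            lines.append(f"  KL{i} {row}")
        return "\n".join(lines)
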