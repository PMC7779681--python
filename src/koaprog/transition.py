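"""Row-stochastic transition matrices over KL grades 0-4."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

N_GRADES = 5

# Only two entries of the default matrix are literature values: an
# at-risk knee (KL=1) maintains its grade with probability 0.78 and
# advances to definite radiographic OA (KL=2) with probability 0.17
# over one annual visit.  The remaining mass of row 1 (0.05) regresses
# to KL=0, and all other rows are package constants: established OA
# (KL>=2) is near-absorbing (stay >= 0.90), no transition skips more
# than one grade upward per visit, and no backward transition exceeds
# the regression rate 0.05.
DEFAULT_KOA_MATRIX = np.array(
    [
        [0.90, 0.10, 0.00, 0.00, 0.00],
        [0.05, 0.78, 0.17, 0.00, 0.00],
        [0.00, 0.02, 0.90, 0.08, 0.00],
        [0.00, 0.00, 0.02, 0.92, 0.06],
        [0.00, 0.00, 0.00, 0.02, 0.98],
    ]
)

DEFAULT_REGRESSION_RATE = 0.05


def _read_maybe_path(source) -> str:
    """Accept either a JSON string or a path to one."""
    if isinstance(source, Path):
        return source.read_text()
    s = str(source)
    if "{" in s or "\n" in s:
        return s
    return Path(s).read_text()


@dataclass
class TransitionMatrix:
    """5x5 row-stochastic matrix indexed by KL grade 0-4."""

    probs: np.ndarray = field(default_factory=lambda: DEFAULT_KOA_MATRIX.copy())

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.probs.shape != (N_GRADES, N_GRADES):
            raise ValueError(f"transition matrix must be {N_GRADES}x{N_GRADES}")
        if (self.probs < 0).any() or (self.probs > 1).any():
            raise ValueError("transition probabilities outside [0, 1]")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12, rtol=0):
            raise ValueError(f"rows must sum to 1, got {sums}")

    def __getitem__(self, idx):
        return self.probs[idx]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"probs": self.probs.tolist()}, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TransitionMatrix":
        text = _read_maybe_path(source)
        return cls(np.array(json.loads(text)["probs"]))


def default_transition_matrix() -> TransitionMatrix:
    """The package's default annual KL-grade transition matrix.

    Row 1 encodes the published one-year dynamics of the at-risk state:
    P(1->1) = 0.78, P(1->2) = 0.17; everything else is a documented
    package constant (see ``DEFAULT_KOA_MATRIX``).
    """
    return TransitionMatrix(DEFAULT_KOA_MATRIX.copy())
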