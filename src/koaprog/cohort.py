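"""Longitudinal cohort container.

A :class:`Cohort` is a long-format patient-visit table: one row per
(patient, visit) with a Kellgren/Lawrence (KL) grade in 0-4 (or missing)
and a set of typed covariates.  It is the common currency of every stage
of the pipeline: the simulator emits one, preprocessing transforms one,
and the Markov, logistic, LSTM and FCI models all consume one.

On disk a cohort is a plain CSV (UTF-8, header row, missing = empty
field) plus a JSON sidecar declaring each covariate's type
(``continuous`` / ``ordinal`` / ``binary``) and, for ordinal variables,
its level set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

KEY_COLUMNS = ("patient_id", "visit", "kl")

VALID_TYPES = ("continuous", "ordinal", "binary")


@dataclass
class CovariateSchema:
    """Type declaration for one covariate."""

    name: str
    kind: str  # continuous | ordinal | binary
    levels: list | None = None  # ordered levels, ordinal/binary only

    def __post_init__(self):
        if self.kind not in VALID_TYPES:
            raise ValueError(f"unknown covariate type {self.kind!r} for {self.name}")

    def to_dict(self) -> dict:
        d = {"type": self.kind}
        if self.levels is not None:
            d["levels"] = list(self.levels)
        return d

    @classmethod
    def from_dict(cls, name: str, d: dict) -> "CovariateSchema":
        return cls(name=name, kind=d["type"], levels=d.get("levels"))


@dataclass
class Cohort:
    """Long-format longitudinal table with a covariate type schema.

    Parameters
    ----------
    data : DataFrame with columns ``patient_id``, ``visit``, ``kl`` and
        one column per covariate.  ``kl`` is integer 0-4 or NaN.
    schema : mapping from covariate name to :class:`CovariateSchema`.
    """

    data: pd.DataFrame
    schema: dict[str, CovariateSchema] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- structural invariants -------------------------------------------
    def validate(self) -> None:
        df = self.data
        for col in KEY_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"cohort is missing required column {col!r}")
        if df.duplicated(subset=["patient_id", "visit"]).any():
            raise ValueError("duplicate (patient_id, visit) pairs")
        kl = df["kl"].dropna()
        if len(kl) and not kl.isin([0, 1, 2, 3, 4]).all():
            raise ValueError("kl values outside 0-4")
        # visits per patient must form a contiguous 0-based range
        vis = df.groupby("patient_id", sort=False)["visit"]
        bad = (vis.min() != 0) | (vis.max() + 1 != vis.count())
        if bad.any():
            offenders = bad[bad].index.tolist()[:5]
            raise ValueError(f"non-contiguous visit range for patients {offenders}")
        for name in self.schema:
            if name not in df.columns:
                raise ValueError(f"schema covariate {name!r} absent from table")

    # -- convenience -----------------------------------------------------
    @property
    def covariates(self) -> list[str]:
        return list(self.schema)

    @property
    def n_patients(self) -> int:
        return self.data["patient_id"].nunique()

    def baseline(self) -> pd.DataFrame:
        """Rows of visit 0 only (one per patient)."""
        return self.data[self.data["visit"] == 0].reset_index(drop=True)

    def copy(self) -> "Cohort":
        return Cohort(self.data.copy(), dict(self.schema))

    def continuous_covariates(self) -> list[str]:
        return [n for n, s in self.schema.items() if s.kind == "continuous"]

    def ordinal_covariates(self) -> list[str]:
        return [n for n, s in self.schema.items() if s.kind in ("ordinal", "binary")]

    # -- IO ---------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV and the schema as a ``.schema.json`` sidecar."""
        path = Path(path)
        self.data.to_csv(path, index=False, na_rep="")
        sidecar = {n: s.to_dict() for n, s in self.schema.items()}
        path.with_suffix(path.suffix + ".schema.json").write_text(
            json.dumps(sidecar, indent=1)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        path = Path(path)
        sidecar_path = path.with_suffix(path.suffix + ".schema.json")
        schema: dict[str, CovariateSchema] = {}
        if sidecar_path.exists():
            raw = json.loads(sidecar_path.read_text())
            schema = {n: CovariateSchema.from_dict(n, d) for n, d in raw.items()}
        df = pd.read_csv(path)
        df["patient_id"] = df["patient_id"].astype(str)
        for name, sch in schema.items():
            if sch.kind in ("ordinal", "binary") and name in df.columns:
                df[name] = df[name].astype("float").astype("Int64").astype("float")
        return cls(df, schema)


def make_cohort_frame(
    patient_ids: np.ndarray, visits: np.ndarray, kl: np.ndarray, covariates: dict
) -> pd.DataFrame:
    """Assemble a cohort frame from parallel per-row arrays."""
    df = pd.DataFrame({"patient_id": patient_ids, "visit": visits, "kl": kl})
    for name, values in covariates.items():
        df[name] = values
    return df
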