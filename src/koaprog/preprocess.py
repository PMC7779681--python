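"""Cohort preprocessing: imputation, knee selection, binning, integration.

Covers the data-preparation conventions of the analysis: missing
covariates are filled by predictive-mean matching, the index knee is
the one with the higher KL grade, BMI and age enter the logistic model
as categorical bins, and covariates absent from one cohort can be
borrowed from an age/BMI-matched donor cohort and then denoised with a
PCA or autoencoder feature extractor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .cohort import Cohort, CovariateSchema

logger = logging.getLogger(__name__)


class ImputationError(ValueError):
    pass


class OutOfRangeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# categorical binning


@dataclass
class BinningScheme:
    """Half-open bins [edge_i, edge_{i+1}) over one continuous variable."""

    variable: str
    edges: list[float]
    labels: list[str]
    reference: str

    def __post_init__(self):
        e = np.asarray(self.edges, float)
        if not (np.diff(e) > 0).all():
            raise ValueError("bin edges must be strictly increasing")
        if len(self.labels) != len(self.edges) - 1:
            raise ValueError("need exactly one label per bin")
        if self.reference not in self.labels:
            raise ValueError("reference label not among bin labels")

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "edges": list(self.edges),
            "labels": list(self.labels),
            "reference": self.reference,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinningScheme":
        return cls(**d)


def bmi_binning() -> BinningScheme:
    """Standard BMI categories with the normal range as reference.

    The gaps in the conventional group limits are closed as half-open
    intervals, and the obese range is split at 40 into obese vs
    morbidly obese (the extra category used in the odds-ratio table).
    """
    return BinningScheme(
        variable="bmi",
        edges=[10, 20, 26, 35, 40, np.inf],
        labels=["underweight", "normal", "overweight", "obese", "morbidly_obese"],
        reference="normal",
    )


def age_binning() -> BinningScheme:
    """Five-year age intervals, 45-49 as the reference bin."""
    return BinningScheme(
        variable="age",
        edges=[45, 50, 55, 60, 65, 70, 75, 80],
        labels=["45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79"],
        reference="45-49",
    )


def bin_variable(values: pd.Series, scheme: BinningScheme) -> pd.Series:
    """Map each value to its bin label; NaNs propagate."""
    arr = values.to_numpy(dtype=float)
    edges = np.asarray(scheme.edges, float)
    idx = np.digitize(arr, edges, right=False) - 1
    finite = ~np.isnan(arr)
    bad = finite & ((idx < 0) | (idx >= len(scheme.labels)))
    if bad.any():
        rows = np.flatnonzero(bad).tolist()
        raise OutOfRangeError(
            f"{scheme.variable}: values outside [{edges[0]}, {edges[-1]}) at rows {rows[:20]}"
        )
    out = np.full(len(arr), None, dtype=object)
    out[finite] = np.asarray(scheme.labels, dtype=object)[idx[finite]]
    return pd.Series(out, index=values.index, name=f"{scheme.variable}_bin")


def save_binning_schemes(schemes: list[BinningScheme], path: str | Path) -> None:
    Path(path).write_text(json.dumps([s.to_dict() for s in schemes], indent=1))


def load_binning_schemes(path: str | Path) -> list[BinningScheme]:
    return [BinningScheme.from_dict(d) for d in json.loads(Path(path).read_text())]


# ---------------------------------------------------------------------------
# index-knee selection


def select_index_knee(left_kl: int, right_kl: int) -> str:
    """Pick the study knee: the one with the strictly higher grade.

    Ties go to the right knee (the questionnaire items retained by the
    selection step are dominated by right-knee items).
    """
    for g in (left_kl, right_kl):
        if g not in (0, 1, 2, 3, 4):
            raise ValueError(f"KL grade {g!r} outside 0-4")
    return "left" if left_kl > right_kl else "right"


# ---------------------------------------------------------------------------
# predictive-mean imputation


def impute_predictive_mean(
    cohort: Cohort,
    k_donors: int = 5,
    seed: int = 0,
    method: str = "pmm",
) -> Cohort:
    """Fill missing covariate cells by predictive-mean matching.

    For each covariate with missing cells, a linear predictor is fitted
    (on rows where the target is observed) from the cohort's fully
    observed covariates; predicted means are computed for every row;
    the donor pool of a missing cell is the ``k_donors`` observed rows
    with nearest predicted mean; the imputed value is a seeded draw
    from the donors (continuous) or the modal donor value (ordinal /
    binary).  Imputed values therefore always lie within the observed
    support of the covariate.  ``method="mean"`` instead fills with the
    predicted mean itself (continuous) or the rounded prediction
    clipped to the observed level set (ordinal).
    """
    if method not in ("pmm", "mean"):
        raise ValueError("method must be 'pmm' or 'mean'")
    out = cohort.copy()
    df = out.data
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))

    covs = out.covariates
    missing_mask = {c: df[c].isna().to_numpy() for c in covs}
    for c in covs:
        n_obs = int((~missing_mask[c]).sum())
        if n_obs == 0:
            raise ImputationError(f"covariate {c!r} is fully missing; cannot impute")
        if n_obs < k_donors:
            raise ImputationError(
                f"covariate {c!r} has {n_obs} observed values < k_donors={k_donors}"
            )
    complete = [c for c in covs if not missing_mask[c].any()]

    for c in covs:
        miss = missing_mask[c]
        if not miss.any():
            continue
        predictors = [p for p in complete if p != c]
        X = np.column_stack(
            [np.ones(len(df))] + [df[p].to_numpy(dtype=float) for p in predictors]
        )
        y = df[c].to_numpy(dtype=float)
        obs = ~miss
        beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
        yhat = X @ beta
        obs_idx = np.flatnonzero(obs)
        obs_pred = yhat[obs_idx]
        obs_val = y[obs_idx]
        is_ordinal = out.schema[c].kind in ("ordinal", "binary")
        filled = y.copy()
        for i in np.flatnonzero(miss):
            d = np.abs(obs_pred - yhat[i])
            pool = np.argsort(d, kind="stable")[:k_donors]
            donors = obs_val[pool]
            if method == "mean":
                if is_ordinal:
                    levels = np.unique(obs_val)
                    filled[i] = levels[np.argmin(np.abs(levels - yhat[i]))]
                else:
                    filled[i] = yhat[i]
            elif is_ordinal:
                vals, cnt = np.unique(donors, return_counts=True)
                filled[i] = vals[np.argmax(cnt)]  # modal donor; ties -> lowest level
            else:
                filled[i] = rng.choice(donors)
        df[c] = filled
    return out


# ---------------------------------------------------------------------------
# cross-cohort matched imputation


def match_impute_cross_cohort(
    target: Cohort,
    donor: Cohort,
    match_vars: tuple[str, str] = ("age_bin", "bmi_bin"),
    new_vars: list[str] | None = None,
) -> Cohort:
    """Borrow covariates from an age/BMI-matched donor cohort.

    Matching is done at baseline: for each target patient, donor
    baseline rows with identical match-variable values are located.
    Exactly one match copies the donor values verbatim; multiple
    matches contribute their arithmetic mean (continuous) or mode
    (ordinal); zero matches leave the new variables missing and log the
    patient id.  Borrowed values are constant across a patient's
    visits.
    """
    if new_vars is None:
        raise ValueError("new_vars must name at least one donor covariate")
    for v in new_vars:
        if v not in donor.schema:
            raise ValueError(f"requested variable {v!r} absent from donor cohort")
    for v in match_vars:
        for c, label in ((target, "target"), (donor, "donor")):
            if v not in c.data.columns:
                raise ValueError(f"match variable {v!r} absent from {label} cohort")

    out = target.copy()
    tb = out.baseline().set_index("patient_id")
    db = donor.baseline()
    groups = db.groupby(list(match_vars))

    assigned: dict[str, dict[str, float]] = {v: {} for v in new_vars}
    for pid, row in tb.iterrows():
        key = tuple(row[v] for v in match_vars)
        try:
            matched = groups.get_group(key)
        except KeyError:
            logger.warning("no donor match for patient %s (key=%s)", pid, key)
            continue
        for v in new_vars:
            vals = matched[v].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                logger.warning("no observed donor values of %s for patient %s", v, pid)
                continue
            if out.schema.get(v, donor.schema[v]).kind == "continuous" or (
                donor.schema[v].kind == "continuous"
            ):
                assigned[v][pid] = float(vals.mean())
            else:
                u, cnt = np.unique(vals, return_counts=True)
                assigned[v][pid] = float(u[np.argmax(cnt)])

    for v in new_vars:
        out.data[v] = out.data["patient_id"].map(assigned[v])
        out.schema[v] = donor.schema[v]
    out.validate()
    return out


# ---------------------------------------------------------------------------
# denoising feature extractors


@dataclass
class DenoiserModel:
    """Fitted denoiser: linear PCA or a one-hidden-layer autoencoder.

    Operates on column-standardized features; ``transform`` maps to the
    latent space and ``inverse_transform`` back to the (standardized)
    input space.
    """

    method: str
    latent_dim: int
    mean_: np.ndarray
    scale_: np.ndarray
    components_: np.ndarray | None = None  # (latent_dim, n_features), PCA
    weights_: dict | None = None  # autoencoder parameters
    history: list[float] = field(default_factory=list)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = self._standardize(np.asarray(X, float))
        if self.method == "pca":
            return Z @ self.components_.T
        W1, b1 = self.weights_["W1"], self.weights_["b1"]
        return np.tanh(Z @ W1 + b1)

    def inverse_transform(self, H: np.ndarray) -> np.ndarray:
        if self.method == "pca":
            return H @ self.components_
        W2, b2 = self.weights_["W2"], self.weights_["b2"]
        return H @ W2 + b2

    def reconstruction_error(self, X: np.ndarray) -> float:
        Z = self._standardize(np.asarray(X, float))
        R = self.inverse_transform(self.transform(X))
        return float(np.mean((Z - R) ** 2))

    def denoise(self, X: np.ndarray) -> np.ndarray:
        """Round-trip through the latent space, back on the original scale."""
        R = self.inverse_transform(self.transform(X))
        return R * self.scale_ + self.mean_


def fit_denoiser(
    features: np.ndarray,
    method: str = "pca",
    latent_dim: int = 2,
    seed: int = 0,
    epochs: int = 300,
    lr: float = 0.05,
) -> DenoiserModel:
    """Fit a denoising feature extractor on a complete numeric matrix.

    PCA is computed from the singular value decomposition of the
    column-standardized matrix (deterministic up to component sign).
    The autoencoder is a single-hidden-layer tanh encoder with a linear
    decoder trained by full-batch gradient descent on the squared
    reconstruction error; the loss history is recorded per epoch.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if np.isnan(X).any():
        raise ValueError("features contain missing cells; impute first")
    n, p = X.shape
    if latent_dim >= p:
        raise ValueError(f"latent_dim must be < n_features ({latent_dim} >= {p})")
    if latent_dim < 1:
        raise ValueError("latent_dim must be >= 1")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale

    if method == "pca":
        _, _, Vt = np.linalg.svd(Z, full_matrices=False)
        comp = Vt[:latent_dim]
        model = DenoiserModel("pca", latent_dim, mean, scale, components_=comp)
        model.history = [model.reconstruction_error(X)]
        return model
    if method != "autoencoder":
        raise ValueError("method must be 'pca' or 'autoencoder'")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
    W1 = rng.normal(0, 0.1, size=(p, latent_dim))
    b1 = np.zeros(latent_dim)
    W2 = rng.normal(0, 0.1, size=(latent_dim, p))
    b2 = np.zeros(p)
    history = []
    for _ in range(epochs):
        H = np.tanh(Z @ W1 + b1)
        R = H @ W2 + b2
        err = R - Z
        loss = float(np.mean(err**2))
        history.append(loss)
        gR = 2 * err / err.size
        gW2 = H.T @ gR
        gb2 = gR.sum(axis=0)
        gH = gR @ W2.T
        gA = gH * (1 - H**2)
        gW1 = Z.T @ gA
        gb1 = gA.sum(axis=0)
        W1 -= lr * gW1
        b1 -= lr * gb1
        W2 -= lr * gW2
        b2 -= lr * gb2
    weights = {"W1": W1, "b1": b1, "W2": W2, "b2": b2}
    model = DenoiserModel("autoencoder", latent_dim, mean, scale, weights_=weights)
    model.history = history + [model.reconstruction_error(X)]
    return model
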