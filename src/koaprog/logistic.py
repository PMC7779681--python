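"""Multivariable logistic regression for incident radiographic KOA.

Fits P(KL > 1) on mixed continuous and categorical predictors and
reports, per coefficient, the odds ratio with its 95% Wald interval and
normal-reference p-value, and per predictor variable a likelihood-ratio
p-value — the table that drives feature selection for the downstream
predictive models.

The fit is iteratively reweighted least squares (IRLS) with an explicit
separation guard: a coefficient diverging past |beta| = 15 is capped and
flagged rather than penalized, because the published odds-ratio tables
this reproduces show unpenalized extreme ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

from .cohort import Cohort
from .preprocess import BinningScheme, bin_variable

Z975 = norm.ppf(0.975)  # 1.959964...
BETA_CAP = 15.0


class SingularDesignError(ValueError):
    pass


class SeparationWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# design encoding


@dataclass
class Design:
    """Encoded feature matrix with variable grouping metadata."""

    X: np.ndarray  # (n, p), no intercept column
    columns: list[str]  # "variable=level" for dummies, plain name otherwise
    groups: dict[str, list[int]]  # variable -> column indices
    reference_levels: dict[str, object]  # categorical variable -> reference

    def drop_variable(self, variable: str) -> "Design":
        keep = [j for j in range(self.X.shape[1]) if j not in self.groups[variable]]
        remap = {}
        for v, idx in self.groups.items():
            if v == variable:
                continue
            remap[v] = [keep.index(j) for j in idx]
        return Design(
            self.X[:, keep],
            [self.columns[j] for j in keep],
            remap,
            {v: r for v, r in self.reference_levels.items() if v != variable},
        )


def encode_categoricals(
    cohort_or_frame,
    schemes: list[BinningScheme] | None = None,
    categorical_references: dict[str, object] | None = None,
) -> Design:
    """Treatment-code a cohort's covariates into a design matrix.

    Continuous covariates pass through unchanged.  Variables named by a
    :class:`BinningScheme` are first binned, then dummy-coded with the
    scheme's reference label dropped.  Ordinal/binary covariates are
    dummy-coded with their lowest level (``no symptom``) as reference
    unless overridden via ``categorical_references``.
    """
    if isinstance(cohort_or_frame, Cohort):
        df = cohort_or_frame.data
        schema = cohort_or_frame.schema
    else:
        df = cohort_or_frame
        schema = {}
    schemes = schemes or []
    refs = dict(categorical_references or {})
    scheme_by_var = {s.variable: s for s in schemes}

    cols: list[np.ndarray] = []
    names: list[str] = []
    groups: dict[str, list[int]] = {}
    ref_out: dict[str, object] = {}

    def add_dummies(var: str, series: pd.Series, levels: list, reference):
        groups[var] = []
        ref_out[var] = reference
        arr = series.to_numpy()
        for lv in levels:
            if lv == reference:
                continue
            indicator = (arr == lv).astype(float)
            if indicator.sum() == 0:
                continue  # unused factor level: no column
            groups[var].append(len(names))
            names.append(f"{var}={lv}")
            cols.append(indicator)
        if not groups[var]:
            del groups[var]  # variable constant at reference: nothing to fit

    for var in [c for c in df.columns if c not in ("patient_id", "visit", "kl")]:
        series = df[var]
        if var in scheme_by_var:
            s = scheme_by_var[var]
            binned = bin_variable(series, s)
            if binned.isna().any():
                raise ValueError(f"cannot encode {var}: missing values present")
            add_dummies(var, binned, s.labels, s.reference)
        elif var in schema and schema[var].kind in ("ordinal", "binary"):
            observed_levels = schema[var].levels or sorted(series.dropna().unique())
            reference = refs.get(var, observed_levels[0])
            if reference not in observed_levels:
                raise ValueError(f"unseen reference level {reference!r} for {var}")
            present = set(series.dropna().unique())
            unseen = present - set(observed_levels)
            if unseen:
                raise ValueError(f"unseen levels {unseen} for {var}")
            add_dummies(var, series, list(observed_levels), reference)
        else:
            groups[var] = [len(names)]
            names.append(var)
            cols.append(series.to_numpy(dtype=float))

    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    if np.isnan(X).any():
        raise ValueError("design contains missing values; impute first")
    return Design(X, names, groups, ref_out)


def decode_row(design: Design, row: np.ndarray) -> dict:
    """Invert the treatment coding of one encoded row back to labels."""
    out = {}
    for var, idx in design.groups.items():
        if var in design.reference_levels:
            hit = [design.columns[j].split("=", 1)[1] for j in idx if row[j] == 1.0]
            out[var] = hit[0] if hit else design.reference_levels[var]
        else:
            out[var] = row[idx[0]]
    return out


# ---------------------------------------------------------------------------
# IRLS fit


def _loglik(X, y, beta):
    mu = expit(X @ beta)
    return float(
        np.sum(y * np.log(np.clip(mu, 1e-300, 1)) + (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1)))
    )


def _irls(X: np.ndarray, y: np.ndarray, max_iter: int, tol: float):
    # IRLS written as a damped Newton step (identical fixed point, but no
    # division by vanishing weights under separation); step-halving keeps
    # the log-likelihood monotone, and diverging coefficients are pinned
    # at +/- BETA_CAP
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    capped = np.zeros(p, dtype=bool)
    ll = _loglik(X, y, beta)
    stalled = 0
    for _ in range(max_iter):
        mu = expit(X @ beta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        fisher = (X.T * w) @ X
        step = np.linalg.solve(fisher, X.T @ (y - mu))
        # the candidate is always the *capped* point, so the line search
        # certifies monotone likelihood for the iterate actually taken
        proposal = beta + step
        for _halve in range(30):
            beta_new = np.clip(proposal, -BETA_CAP, BETA_CAP)
            if _loglik(X, y, beta_new) >= ll - 1e-12:
                break
            proposal = (beta + proposal) / 2
        capped |= np.abs(proposal) > BETA_CAP
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        ll_prev, ll = ll, _loglik(X, y, beta)
        # primary criterion: coefficient stability; under quasi-separation
        # the flat directions can crawl or micro-cycle forever, so a
        # sustained log-likelihood plateau also counts as convergence
        stalled = stalled + 1 if ll - ll_prev < 1e-9 * (1 + abs(ll)) else 0
        if delta < tol or stalled >= 5:
            converged = True
            break
    mu = expit(X @ beta)
    ll = float(np.sum(y * np.log(np.clip(mu, 1e-300, 1)) + (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1))))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    fisher = (X.T * w) @ X
    cov = np.linalg.inv(fisher)
    return beta, np.sqrt(np.diag(cov)), ll, converged, capped


def _check_rank(X: np.ndarray, columns: list[str]) -> None:
    if X.shape[1] == 0:
        return
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name the columns whose removal restores full rank
        _, Rd = np.linalg.qr(X)
        diag = np.abs(np.diag(Rd))
        bad = [columns[j] for j in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise SingularDesignError(f"design is rank deficient; collinear columns: {bad}")


@dataclass
class TermResult:
    variable: str
    level: object  # None for continuous terms
    coef: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    wald_p: float
    separation_flag: bool = False


@dataclass
class LogisticReport:
    """Per-term odds ratios and per-variable LRT p-values."""

    terms: list[TermResult]
    variable_lrt: dict[str, float]
    loglik: float
    n: int
    converged: bool
    reference_levels: dict[str, object]
    intercept: TermResult | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            rows.append(
                {
                    "variable": t.variable,
                    "level": t.level,
                    "coef": t.coef,
                    "odds_ratio": t.odds_ratio,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "wald_p": t.wald_p,
                    "lrt_p": self.variable_lrt.get(t.variable, np.nan),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Multivariable logistic regression: independent predictors of KL > 1",
            f"  n = {self.n}   log-likelihood = {self.loglik:.3f}   converged = {self.converged}",
            f"{'predictor':<28}{'OR':>8}{'[95% conf.':>12}{'interval]':>11}{'p>z':>10}{'p(>Chi)':>10}",
        ]
        for _, r in df.iterrows():
            name = r["variable"] if pd.isna(r["level"]) or r["level"] is None else f"{r['variable']}={r['level']}"
            lines.append(
                f"{name:<28}{r['odds_ratio']:>9.3g}{r['ci_low']:>12.3g}{r['ci_high']:>11.3g}"
                f"{r['wald_p']:>10.4f}{r['lrt_p']:>10.4f}"
            )
        return "\n".join(lines)


def fit_logistic(
    design: Design,
    outcome: np.ndarray,
    max_iter: int = 300,
    tol: float = 1e-10,
) -> LogisticReport:
    """Fit the logistic model by IRLS and assemble the report.

    95% intervals are exp(beta +/- 1.959964 * SE); per-variable LRT
    p-values come from refitting without that variable's columns, with
    degrees of freedom equal to the number of columns dropped.
    """
    y = np.asarray(outcome, float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be strictly binary (0/1)")
    X = np.column_stack([np.ones(len(y)), design.X])
    columns = ["intercept"] + design.columns
    _check_rank(X, columns)
    beta, se, ll, converged, capped = _irls(X, y, max_iter, tol)
    if capped.any():
        for j in np.flatnonzero(capped):
            warnings.warn(
                f"possible complete separation on term {columns[j]!r}; "
                f"coefficient capped at |beta|={BETA_CAP}",
                SeparationWarning,
                stacklevel=2,
            )

    def make_term(j: int, variable: str, level) -> TermResult:
        b, s = beta[j], se[j]
        z = b / s if s > 0 else np.inf
        with np.errstate(over="ignore"):  # a separated CI may overflow to inf
            return TermResult(
            variable=variable,
            level=level,
            coef=b,
            se=s,
            odds_ratio=float(np.exp(b)),
            ci_low=float(np.exp(b - Z975 * s)),
            ci_high=float(np.exp(b + Z975 * s)),
            wald_p=float(2 * norm.sf(abs(z))),
            separation_flag=bool(capped[j]),
        )

    intercept = make_term(0, "intercept", None)
    terms = []
    for var, idx in design.groups.items():
        for j in idx:
            name = design.columns[j]
            level = name.split("=", 1)[1] if "=" in name else None
            terms.append(make_term(j + 1, var, level))

    lrt: dict[str, float] = {}
    for var, idx in design.groups.items():
        reduced = design.drop_variable(var)
        Xr = np.column_stack([np.ones(len(y)), reduced.X])
        _, _, ll_r, _, _ = _irls(Xr, y, max_iter, tol)
        stat = max(0.0, 2 * (ll - ll_r))
        lrt[var] = float(chi2.sf(stat, df=len(idx)))

    return LogisticReport(
        terms=terms,
        variable_lrt=lrt,
        loglik=ll,
        n=len(y),
        converged=converged,
        reference_levels=dict(design.reference_levels),
        intercept=intercept,
    )


def remove_weak_predictors(report: LogisticReport, alpha: float = 0.5) -> list[str]:
    """Variables providing no evidence at level ``alpha``.

    A variable is flagged for removal when its likelihood-ratio p-value
    exceeds ``alpha`` *and* every one of its per-level Wald p-values
    does too; downstream predictive models drop the returned list.
    """
    if not report.converged:
        raise ValueError("report did not converge; refusing selection")
    removed = []
    by_var: dict[str, list[TermResult]] = {}
    for t in report.terms:
        by_var.setdefault(t.variable, []).append(t)
    for var, terms in by_var.items():
        lrt_p = report.variable_lrt.get(var, np.nan)
        if lrt_p > alpha and all(t.wald_p > alpha for t in terms):
            removed.append(var)
    return removed


# ---------------------------------------------------------------------------
# model facade


class LogisticSelectionModel:
    """KL > 1 logistic model over a cohort (statsmodels-style facade).

    Parameters
    ----------
    cohort : the (imputed) cohort to fit on.
    schemes : binning schemes applied to continuous variables entering
        as categories (BMI, age).
    visit : ``"baseline"`` fits on visit 0 only (default); ``"pooled"``
        treats every patient-visit row as an observation.
    """

    def __init__(
        self,
        cohort: Cohort,
        schemes: list[BinningScheme] | None = None,
        visit: str = "baseline",
        categorical_references: dict[str, object] | None = None,
    ):
        if visit not in ("baseline", "pooled"):
            raise ValueError("visit must be 'baseline' or 'pooled'")
        self.cohort = cohort
        self.schemes = schemes or []
        self.visit = visit
        self.categorical_references = categorical_references

    def _frame(self) -> pd.DataFrame:
        return self.cohort.baseline() if self.visit == "baseline" else self.cohort.data

    def fit(self, max_iter: int = 300, tol: float = 1e-10) -> LogisticReport:
        df = self._frame()
        sub = Cohort(df.reset_index(drop=True), dict(self.cohort.schema))
        design = encode_categoricals(sub, self.schemes, self.categorical_references)
        outcome = (df["kl"].to_numpy(dtype=float) > 1).astype(float)
        if df["kl"].isna().any():
            raise ValueError("missing KL grades in the fitting frame")
        return fit_logistic(design, outcome, max_iter=max_iter, tol=tol)
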