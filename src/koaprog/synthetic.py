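"""Synthetic longitudinal KOA cohorts with known causal structure.

This module generates cohorts that emulate an OAI-style longitudinal
study of knee osteoarthritis: annual visits, a Kellgren/Lawrence grade
evolving as a monotone-tending Markov chain, and mixed radiographic /
clinical / questionnaire covariates tied together by a known structural
causal model.  Because the generating Markov matrix and causal graph are
known, every downstream stage (transition estimation, logistic
selection, LSTM prediction, FCI discovery) can be tested for *recovery*
rather than against inaccessible clinical data.

The default structural model encodes the qualitative causal story of
knee OA progression:

* a latent anatomical factor confounds left and right knee alignment
  (so the alignment pair is latently confounded, which FCI should
  report as a bidirected edge);
* tibiofemoral / patellofemoral joint angles are observed causes of the
  two alignments;
* alignment causes joint-space narrowing (JSN), the radiographic proxy
  for cartilage loss;
* JSN, BMI and age drive KL progression (a logit shift on the advance
  probability of the Markov chain);
* symptoms (swelling, grinding, catching, limited flexion) and pain are
  *consequences* of the current KL grade and have no causal path into
  progression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.special import expit, logit

from .cohort import Cohort, CovariateSchema, make_cohort_frame
from .transition import TransitionMatrix, default_transition_matrix

__all__ = [
    "Node",
    "HazardTerm",
    "CausalSpec",
    "default_causal_spec",
    "default_transition_matrix",
    "simulate_cohort",
    "inject_missingness",
]


@dataclass
class Node:
    """One structural equation.

    continuous:  value = intercept + sum(coef * parent) + Normal(0, noise_sd)
    ordinal:     latent = intercept + sum(coef * parent) + Logistic(0, 1);
                 level  = number of thresholds below the latent score.
    markov:      reserved for the KL grade, driven by the transition
                 matrix (see :func:`simulate_cohort`).
    """

    name: str
    kind: str  # continuous | ordinal | markov
    parents: list[str] = field(default_factory=list)
    coefs: list[float] = field(default_factory=list)
    intercept: float = 0.0
    noise_sd: float = 1.0
    thresholds: list[float] = field(default_factory=list)
    observed: bool = True
    time_varying: bool = False
    # enrollment-style truncation of a continuous node (clip after noise)
    bounds: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "ordinal", "markov"):
            raise ValueError(f"unknown mechanism kind {self.kind!r}")
        if len(self.parents) != len(self.coefs) and self.kind != "markov":
            raise ValueError(f"node {self.name}: parents/coefs length mismatch")


@dataclass
class HazardTerm:
    """One covariate's multiplicative (logit-scale) effect on KL advance.

    Contributes ``coef * (value - center) / scale`` to the logit shift
    applied to the one-step-up transition probability.
    """

    node: str
    coef: float
    center: float = 0.0
    scale: float = 1.0


@dataclass
class CausalSpec:
    """Ground-truth causal model: nodes, structural equations, KL hazard."""

    nodes: list[Node]
    hazard: list[HazardTerm] = field(default_factory=list)
    kl_initial_dist: list[float] = field(
        default_factory=lambda: [0.35, 0.30, 0.20, 0.10, 0.05]
    )
    seed: int = 0

    def __post_init__(self):
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names")
        name_set = set(names)
        for n in self.nodes:
            missing = set(n.parents) - name_set
            if missing:
                raise ValueError(f"node {n.name} references undeclared parents {missing}")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("causal specification contains a cycle")
        for term in self.hazard:
            if term.node not in name_set:
                raise ValueError(
                    f"hazard modulation references unknown node {term.node!r}"
                )
        dist = np.asarray(self.kl_initial_dist, float)
        if dist.shape != (5,) or not np.isclose(dist.sum(), 1.0):
            raise ValueError("kl_initial_dist must be 5 probabilities summing to 1")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(n.name for n in self.nodes)
        for n in self.nodes:
            for p in n.parents:
                g.add_edge(p, n.name)
        return g

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph().edges())

    def node(self, name: str) -> Node:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    @property
    def observed_nodes(self) -> list[str]:
        return [n.name for n in self.nodes if n.observed]

    # -- IO ---------------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "nodes": [vars(n) for n in self.nodes],
            "hazard": [vars(t) for t in self.hazard],
            "kl_initial_dist": list(self.kl_initial_dist),
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CausalSpec":
        from .transition import _read_maybe_path

        d = json.loads(_read_maybe_path(source))
        return cls(
            nodes=[Node(**n) for n in d["nodes"]],
            hazard=[HazardTerm(**t) for t in d["hazard"]],
            kl_initial_dist=d["kl_initial_dist"],
            seed=d.get("seed", 0),
        )


def default_causal_spec() -> CausalSpec:
    """Default ground-truth KOA causal model (coefficients are package
    constants; the qualitative structure is the clinically motivated one
    described in the module docstring)."""
    nodes = [
        Node("age", "continuous", intercept=62.0, noise_sd=8.0, bounds=(45.0, 79.5)),
        Node("bmi", "continuous", intercept=28.0, noise_sd=5.0, bounds=(12.0, 55.0)),
        # latent anatomical confounder of the two knee alignments
        Node("u_align", "continuous", observed=False),
        Node("tf_angle", "continuous"),
        Node("pf_angle", "continuous"),
        Node(
            "left_alignment",
            "continuous",
            parents=["u_align", "tf_angle"],
            coefs=[0.8, 0.8],
            noise_sd=0.6,
        ),
        Node(
            "right_alignment",
            "continuous",
            parents=["u_align", "pf_angle"],
            coefs=[0.8, 0.8],
            noise_sd=0.6,
        ),
        Node(
            "jsn",
            "continuous",
            parents=["left_alignment", "right_alignment"],
            coefs=[0.6, 0.6],
            noise_sd=0.7,
        ),
        Node("kl", "markov"),
        # symptoms: ordinal 0-4 severity items caused by the current grade
        Node(
            "swelling",
            "ordinal",
            parents=["kl"],
            coefs=[1.2],
            thresholds=[1.0, 2.5, 4.0, 5.5],
            time_varying=True,
        ),
        Node(
            "grinding",
            "ordinal",
            parents=["kl"],
            coefs=[1.2],
            thresholds=[0.5, 2.0, 3.5, 5.0],
            time_varying=True,
        ),
        Node(
            "catching",
            "ordinal",
            parents=["kl"],
            coefs=[1.2],
            thresholds=[1.5, 3.0, 4.5, 6.0],
            time_varying=True,
        ),
        Node(
            "limited_flexion",
            "ordinal",
            parents=["kl"],
            coefs=[1.2],
            thresholds=[1.0, 3.0, 5.0, 7.0],
            time_varying=True,
        ),
        # WOMAC-style pain score, continuous consequence of grade
        Node(
            "pain",
            "continuous",
            parents=["kl"],
            coefs=[1.5],
            noise_sd=2.0,
            time_varying=True,
        ),
    ]
    hazard = [
        HazardTerm("jsn", 0.8, center=0.0, scale=1.46),
        HazardTerm("bmi", 0.4, center=28.0, scale=5.0),
        HazardTerm("age", 0.4, center=62.0, scale=8.0),
    ]
    return CausalSpec(nodes=nodes, hazard=hazard)


# ---------------------------------------------------------------------------
# simulation


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Independent, reproducible substream for one (node, visit) slot."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def _sample_node(node: Node, values: dict[str, np.ndarray], n: int,
                 rng: np.random.Generator) -> np.ndarray:
    score = np.full(n, node.intercept, dtype=float)
    for p, c in zip(node.parents, node.coefs):
        score += c * values[p]
    if node.kind == "continuous":
        out = score + rng.normal(0.0, node.noise_sd, size=n)
        if node.bounds is not None:
            out = np.clip(out, *node.bounds)
        return out
    # ordered logit: latent score + standard logistic noise cut at thresholds
    latent = score + rng.logistic(0.0, 1.0, size=n)
    return (latent[:, None] > np.asarray(node.thresholds)[None, :]).sum(axis=1).astype(float)


def _hazard_shift(spec: CausalSpec, values: dict[str, np.ndarray], n: int) -> np.ndarray:
    shift = np.zeros(n)
    for term in spec.hazard:
        shift += term.coef * (values[term.node] - term.center) / term.scale
    return shift


def _sample_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Vectorized draw: one category per row of ``probs``."""
    u = rng.random(probs.shape[0])
    return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)


def _initial_kl(spec: CausalSpec, shift: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """KL(0) from the configured initial distribution, shifted on the
    latent logistic scale by the patient's hazard score (so baseline
    grade carries the same covariate dependence as progression).  At
    shift 0 the marginal distribution is exactly ``kl_initial_dist``."""
    cum = np.cumsum(spec.kl_initial_dist)[:-1]
    cuts = logit(np.clip(cum, 1e-12, 1 - 1e-12))
    latent = shift + rng.logistic(0.0, 1.0, size=shift.shape[0])
    return (latent[:, None] > cuts[None, :]).sum(axis=1)


def _step_kl(kl: np.ndarray, tm: TransitionMatrix, shift: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One annual transition; the one-step-up probability is shifted on
    the logit scale by the hazard score, compensated on the stay entry."""
    probs = tm.probs[kl].copy()
    n = kl.shape[0]
    adv_idx = np.minimum(kl + 1, 4)
    can_advance = (kl < 4) & (probs[np.arange(n), adv_idx] > 0)
    p_adv = probs[np.arange(n), adv_idx]
    with np.errstate(divide="ignore"):
        new_adv = np.where(can_advance, expit(logit(np.clip(p_adv, 1e-12, 1 - 1e-12)) + shift), p_adv)
    # keep rows stochastic: the change in advance mass comes out of 'stay'
    stay = probs[np.arange(n), kl]
    delta = np.where(can_advance, new_adv - p_adv, 0.0)
    delta = np.clip(delta, -p_adv, stay)  # never drive stay or advance negative
    probs[np.arange(n), adv_idx] = p_adv + delta
    probs[np.arange(n), kl] = stay - delta
    return _sample_categorical(rng, probs)


def simulate_cohort(
    spec: CausalSpec,
    tm: TransitionMatrix,
    n_patients: int,
    n_visits: int,
    seed: int,
    modulate: bool = True,
) -> Cohort:
    """Simulate a longitudinal cohort under ``spec`` and ``tm``.

    Baseline covariates are drawn once per patient from the structural
    equations; KL(0) comes from the configured initial distribution
    (hazard-shifted when ``modulate``); KL(t+1) is sampled from the
    transition matrix with the advance probability modulated
    multiplicatively on the logit scale by the hazard score; symptom and
    pain nodes are re-sampled at every visit from their structural
    equations given the current grade.  Deterministic given ``seed``
    (per-node, per-visit substreams; patient *i* occupies position *i*
    of every stream).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if n_visits < 2:
        raise ValueError("n_visits must be >= 2")
    spec.validate()
    tm.validate()

    order = list(nx.topological_sort(spec.graph()))
    node_index = {name: i for i, name in enumerate(order)}
    n = n_patients

    # static (time-invariant, non-markov) nodes in topological order;
    # the KL chain and the time-varying nodes that depend on it follow
    values: dict[str, np.ndarray] = {}
    markov_nodes = [nd for nd in spec.nodes if nd.kind == "markov"]
    if len(markov_nodes) != 1:
        raise ValueError("spec must contain exactly one markov ('kl') node")
    for name in order:
        node = spec.node(name)
        if node.kind == "markov" or node.time_varying:
            continue
        rng = _stream(seed, 1, node_index[name], 0)
        values[name] = _sample_node(node, values, n, rng)

    shift0 = _hazard_shift(spec, values, n) if modulate else np.zeros(n)
    kl_t = _initial_kl(spec, shift0, _stream(seed, 1, node_index[markov_nodes[0].name], 0))
    values["kl"] = kl_t.astype(float)

    static_names = [
        nd.name for nd in spec.nodes if nd.observed and not nd.time_varying and nd.kind != "markov"
    ]
    varying = [nd for nd in spec.nodes if nd.time_varying and nd.kind != "markov"]
    hazard_shift = _hazard_shift(spec, values, n) if modulate else np.zeros(n)

    rows_kl = np.empty((n_visits, n), dtype=int)
    rows_var = {nd.name: np.empty((n_visits, n)) for nd in varying}
    for t in range(n_visits):
        if t > 0:
            kl_t = _step_kl(kl_t, tm, hazard_shift, _stream(seed, 2, 0, t))
        rows_kl[t] = kl_t
        values["kl"] = kl_t.astype(float)
        for nd in varying:
            rng = _stream(seed, 1, node_index[nd.name], t)
            rows_var[nd.name][t] = _sample_node(nd, values, n, rng)

    pid = np.array([f"P{i:06d}" for i in range(n)])
    patient_col = np.repeat(pid, n_visits)
    visit_col = np.tile(np.arange(n_visits), n)
    kl_col = rows_kl.T.reshape(-1)
    covs: dict[str, np.ndarray] = {}
    for name in static_names:
        covs[name] = np.repeat(values[name], n_visits)
    for name, arr in rows_var.items():
        covs[name] = arr.T.reshape(-1)

    schema = {}
    for nd in spec.nodes:
        if not nd.observed or nd.kind == "markov":
            continue
        if nd.kind == "continuous":
            schema[nd.name] = CovariateSchema(nd.name, "continuous")
        else:
            schema[nd.name] = CovariateSchema(
                nd.name, "ordinal", levels=list(range(len(nd.thresholds) + 1))
            )

    df = make_cohort_frame(patient_col, visit_col, kl_col.astype(float), covs)
    return Cohort(df, schema)


def inject_missingness(
    cohort: Cohort, rate: float, mechanism: str = "MCAR", seed: int = 0
) -> Cohort:
    """Mask covariate cells completely at random.

    Each non-key covariate cell is independently set missing with
    probability ``rate``; the KL grade and the (patient, visit) keys are
    never masked.
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    if mechanism != "MCAR":
        raise ValueError(f"unsupported missingness mechanism {mechanism!r}")
    out = cohort.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    n = len(out.data)
    for name in out.covariates:
        mask = rng.random(n) < rate
        col = out.data[name].to_numpy(dtype=float, copy=True)
        col[mask] = np.nan
        out.data[name] = col
    return out
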