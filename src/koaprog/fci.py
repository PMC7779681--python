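"""Fast Causal Inference (FCI) from scratch.

Constraint-based discovery of a partial ancestral graph (PAG) over
cohort variables, allowing latent confounders: conditional-independence
tests (Fisher-z for continuous data, G-squared for contingency data, a
d-separation oracle for verification), PC-style skeleton search with
separating sets, v-structure orientation, a Possible-D-SEP skeleton
refinement pass, and Zhang's orientation rules R1-R4 applied to a fixed
point.

Endpoint marks follow the PAG convention: ``o`` (circle, undetermined),
``>`` (arrowhead, the far variable is not an ancestor of this one) and
``-`` (tail, ancestor).  A bidirected edge (arrowheads at both ends)
indicates at least one unmeasured confounder of the pair.

Determinism: variables are processed in canonical sorted-name order and
conditioning subsets in lexicographic order, so results are invariant
to the input column order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .cohort import Cohort

logger = logging.getLogger(__name__)

CIRCLE, ARROW, TAIL = "o", ">", "-"


# ---------------------------------------------------------------------------
# conditional-independence tests


@dataclass
class CITestResult:
    x: str
    y: str
    s: frozenset
    statistic: float
    p_value: float
    independent: bool
    family: str


class CITester:
    """Base conditional-independence tester at a fixed level alpha."""

    family = "abstract"

    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha
        self.n_tests = 0

    def test(self, x: str, y: str, s) -> CITestResult:
        raise NotImplementedError

    def _result(self, x, y, s, stat, p) -> CITestResult:
        self.n_tests += 1
        return CITestResult(x, y, frozenset(s), float(stat), float(p), bool(p > self.alpha), self.family)


class FisherZTest(CITester):
    """Partial-correlation z-test, exact for multivariate Gaussian data.

    The partial correlation of (x, y) given S is read off the inverse of
    the correlation submatrix over {x, y} + S; the test statistic is
    z = 0.5 * ln((1+r)/(1-r)) * sqrt(n - |S| - 3) against a standard
    normal.
    """

    family = "fisher_z"

    def __init__(self, data: pd.DataFrame, alpha: float = 0.01):
        super().__init__(alpha)
        self.columns = list(data.columns)
        self.index = {c: i for i, c in enumerate(self.columns)}
        self.n = len(data)
        self.corr = np.corrcoef(data.to_numpy(dtype=float), rowvar=False)

    def test(self, x: str, y: str, s) -> CITestResult:
        s = sorted(s)
        if len(s) >= self.n - 3:
            raise ValueError(f"conditioning set too large for n={self.n}: {s}")
        if not s:
            r = self.corr[self.index[x], self.index[y]]
        else:
            idx = [self.index[x], self.index[y]] + [self.index[v] for v in s]
            sub = self.corr[np.ix_(idx, idx)]
            try:
                prec = np.linalg.inv(sub)
            except np.linalg.LinAlgError as e:
                raise np.linalg.LinAlgError(
                    f"singular correlation submatrix for ({x}, {y} | {s})"
                ) from e
            r = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        z = 0.5 * np.log((1 + r) / (1 - r)) * np.sqrt(self.n - len(s) - 3)
        p = 2 * norm.sf(abs(z))
        return self._result(x, y, s, z, p)


class GSquaredTest(CITester):
    """Likelihood-ratio (G^2) independence test for discrete variables,
    stratified over the conditioning set.  Degrees of freedom are
    (lx-1)(ly-1) per non-empty stratum; empty strata reduce the df with
    a warning."""

    family = "g_squared"

    def __init__(self, data: pd.DataFrame, alpha: float = 0.01):
        super().__init__(alpha)
        self.data = data
        self.levels = {c: np.unique(data[c].dropna().to_numpy()) for c in data.columns}

    def test(self, x: str, y: str, s) -> CITestResult:
        s = sorted(s)
        df_data = self.data
        lx, ly = len(self.levels[x]), len(self.levels[y])
        full_strata = int(np.prod([len(self.levels[v]) for v in s])) if s else 1
        groups = [g for _, g in df_data.groupby(s, observed=True)] if s else [df_data]
        g2 = 0.0
        used = 0
        for g in groups:
            table = pd.crosstab(g[x], g[y]).to_numpy(dtype=float)
            if table.sum() == 0 or table.shape[0] < 2 or table.shape[1] < 2:
                continue
            rows = table.sum(axis=1, keepdims=True)
            cols = table.sum(axis=0, keepdims=True)
            expected = rows @ cols / table.sum()
            if (expected < 1).any():
                logger.debug("g_squared: expected cell count < 1 in a stratum of (%s,%s|%s)", x, y, s)
            obs = table[table > 0]
            exp = expected[table > 0]
            g2 += 2 * np.sum(obs * np.log(obs / exp))
            used += 1
        if used < full_strata:
            warnings.warn(
                f"g_squared ({x},{y}|{s}): {full_strata - used} empty/degenerate "
                "strata; degrees of freedom reduced",
                stacklevel=2,
            )
        df = max(1, (lx - 1) * (ly - 1) * max(used, 1))
        p = chi2.sf(g2, df)
        return self._result(x, y, s, g2, p)


class DSeparationOracle(CITester):
    """Perfect CI oracle from d-separation on a known DAG (for tests)."""

    family = "oracle"

    def __init__(self, dag: nx.DiGraph, observed: list[str] | None = None):
        super().__init__(alpha=0.5)
        self.dag = dag
        self.columns = sorted(observed if observed is not None else dag.nodes())

    def test(self, x: str, y: str, s) -> CITestResult:
        sep = nx.is_d_separator(self.dag, {x}, {y}, set(s))
        p = 1.0 if sep else 0.0
        return self._result(x, y, s, 0.0, p)


def ci_test(
    data: pd.DataFrame,
    x: str,
    y: str,
    s,
    family: str = "fisher_z",
    alpha: float = 0.01,
) -> CITestResult:
    """One-shot conditional-independence test (functional wrapper)."""
    tester = make_tester(data, family, alpha)
    return tester.test(x, y, s)


def make_tester(data: pd.DataFrame, family: str, alpha: float) -> CITester:
    if family == "fisher_z":
        return FisherZTest(data, alpha)
    if family == "g_squared":
        return GSquaredTest(data, alpha)
    raise ValueError(f"unknown test family {family!r}")


# ---------------------------------------------------------------------------
# PAG


class PAG:
    """Partial ancestral graph: symmetric adjacency with endpoint marks."""

    def __init__(self, nodes):
        self.nodes = sorted(nodes)
        self._marks: dict[tuple[str, str], str] = {}  # (a, b) -> mark at b

    # -- structure -------------------------------------------------------
    def add_edge(self, a: str, b: str, mark_a: str = CIRCLE, mark_b: str = CIRCLE):
        if a == b:
            raise ValueError("self-edges are not allowed")
        self._marks[(a, b)] = mark_b
        self._marks[(b, a)] = mark_a

    def remove_edge(self, a: str, b: str):
        self._marks.pop((a, b), None)
        self._marks.pop((b, a), None)

    def has_edge(self, a: str, b: str) -> bool:
        return (a, b) in self._marks

    def adjacent(self, a: str) -> list[str]:
        return sorted(b for (x, b) in self._marks if x == a)

    def edges(self) -> list[tuple[str, str]]:
        return sorted({tuple(sorted((a, b))) for (a, b) in self._marks})

    # -- marks -----------------------------------------------------------
    def mark(self, a: str, b: str) -> str:
        """The endpoint mark at ``b`` on the edge a *-* b."""
        return self._marks[(a, b)]

    def set_mark(self, a: str, b: str, mark: str) -> bool:
        """Set the mark at ``b`` on edge a *-* b.  Arrowheads win
        conflicts (an existing arrowhead is never downgraded); returns
        True when the mark actually changed."""
        cur = self._marks[(a, b)]
        if cur == mark:
            return False
        if cur != CIRCLE:
            warnings.warn(
                f"orientation conflict on {a}*-*{b} at {b}: {cur!r} vs {mark!r}; "
                "keeping the more informative arrowhead",
                stacklevel=2,
            )
            if cur == ARROW or mark == CIRCLE:
                return False
        self._marks[(a, b)] = mark
        return True

    def is_bidirected(self, a: str, b: str) -> bool:
        return (
            self.has_edge(a, b)
            and self.mark(a, b) == ARROW
            and self.mark(b, a) == ARROW
        )

    def is_directed(self, a: str, b: str) -> bool:
        """a --> b (tail at a, arrowhead at b)."""
        return self.has_edge(a, b) and self.mark(b, a) == TAIL and self.mark(a, b) == ARROW

    def copy(self) -> "PAG":
        g = PAG(self.nodes)
        g._marks = dict(self._marks)
        return g

    def skeleton(self) -> dict[str, set[str]]:
        return {v: set(self.adjacent(v)) for v in self.nodes}

    def __eq__(self, other) -> bool:
        return isinstance(other, PAG) and self.nodes == other.nodes and self._marks == other._marks

    # -- IO ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": a,
                "target": b,
                "mark_at_source": self.mark(b, a),
                "mark_at_target": self.mark(a, b),
            }
            for a, b in self.edges()
        ]
        return pd.DataFrame(rows, columns=["source", "target", "mark_at_source", "mark_at_target"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b in self.edges():
            g.add_edge(a, b, mark_at_source=self.mark(b, a), mark_at_target=self.mark(a, b), source=a)
        nx.write_graphml(g, path)

    def __repr__(self):
        sym = {CIRCLE: "o", ARROW: ">", TAIL: "-"}
        parts = []
        for a, b in self.edges():
            left = {CIRCLE: "o", ARROW: "<", TAIL: "-"}[self.mark(b, a)]
            parts.append(f"{a} {left}-{sym[self.mark(a, b)]} {b}")
        return f"PAG({len(self.nodes)} nodes: " + "; ".join(parts) + ")"


SepsetStore = dict  # frozenset({x, y}) -> set of separating variables


# ---------------------------------------------------------------------------
# skeleton search


def _pc_skeleton(tester: CITester, nodes: list[str], max_depth: int):
    adj = {v: set(nodes) - {v} for v in nodes}
    sepsets: SepsetStore = {}
    depth = 0
    while depth <= max_depth:
        any_candidate = False
        for x in sorted(nodes):
            for y in sorted(adj[x]):
                candidates = sorted(adj[x] - {y})
                if len(candidates) < depth:
                    continue
                any_candidate = True
                for s in combinations(candidates, depth):
                    res = tester.test(x, y, s)
                    if res.independent:
                        adj[x].discard(y)
                        adj[y].discard(x)
                        sepsets[frozenset((x, y))] = set(s)
                        break
                else:
                    continue
        if not any_candidate:
            break
        depth += 1
    return adj, sepsets


def learn_skeleton(
    data_or_tester,
    family: str = "fisher_z",
    alpha: float = 0.01,
    max_depth: int = 3,
    possible_dsep: bool = True,
):
    """Learn the FCI skeleton and separating sets.

    PC-style search at increasing conditioning-set size with
    deterministic lexicographic ordering; when ``possible_dsep`` is
    set, v-structures are provisionally oriented and every remaining
    edge is retested against subsets (size <= ``max_depth``) of the
    Possible-D-SEP sets of its endpoints, as full FCI requires under
    latent confounding.

    Accepts either a DataFrame (a tester of ``family`` at ``alpha`` is
    constructed) or a ready :class:`CITester` (e.g. the d-separation
    oracle).  Returns ``(adjacency dict, sepset store)``.
    """
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    tester = (
        data_or_tester
        if isinstance(data_or_tester, CITester)
        else make_tester(data_or_tester, family, alpha)
    )
    nodes = sorted(tester.columns)
    adj, sepsets = _pc_skeleton(tester, nodes, max_depth)

    if possible_dsep:
        pag = orient_v_structures(adj, sepsets)
        for x in nodes:
            pds = sorted(possible_d_sep(pag, x))
            for y in sorted(adj[x]):
                cand = [v for v in pds if v != y]
                removed = False
                for d in range(1, max_depth + 1):
                    for s in combinations(cand, d):
                        res = tester.test(x, y, s)
                        if res.independent:
                            adj[x].discard(y)
                            adj[y].discard(x)
                            sepsets[frozenset((x, y))] = set(s)
                            removed = True
                            break
                    if removed:
                        break
    return adj, sepsets


def possible_d_sep(pag: PAG, x: str) -> set[str]:
    """Possible-D-SEP(x): vertices v with a path from x on which every
    intermediate vertex is a collider or part of a triangle."""
    out: set[str] = set()
    # walk over ordered vertex pairs (prev, cur); expand while the triple
    # (prev, cur, nxt) is a collider or a triangle
    start = [(x, v) for v in pag.adjacent(x)]
    seen = set(start)
    frontier = start
    while frontier:
        new = []
        for prev, cur in frontier:
            out.add(cur)
            for nxt in pag.adjacent(cur):
                if nxt in (prev, x) or (cur, nxt) in seen:
                    continue
                collider = pag.mark(prev, cur) == ARROW and pag.mark(nxt, cur) == ARROW
                triangle = pag.has_edge(prev, nxt)
                if collider or triangle:
                    seen.add((cur, nxt))
                    new.append((cur, nxt))
        frontier = new
    return out


# ---------------------------------------------------------------------------
# orientation


def orient_v_structures(skeleton: dict[str, set[str]], sepsets: SepsetStore) -> PAG:
    """Initialize all marks to circles, then orient every unshielded
    triple a - b - c with b outside sepset(a, c) as a *-> b <-* c."""
    nodes = sorted(skeleton)
    pag = PAG(nodes)
    for a in nodes:
        for b in sorted(skeleton[a]):
            if a < b:
                pag.add_edge(a, b)
    for b in nodes:
        neigh = sorted(skeleton[b])
        for a, c in combinations(neigh, 2):
            if c in skeleton[a]:
                continue  # shielded
            key = frozenset((a, c))
            if key in sepsets and b not in sepsets[key]:
                pag.set_mark(a, b, ARROW)
                pag.set_mark(c, b, ARROW)
    return pag


def _rule1(pag: PAG) -> bool:
    """a *-> b o-* c, a and c non-adjacent  =>  b -> c."""
    changed = False
    for b in pag.nodes:
        for a in pag.adjacent(b):
            if pag.mark(a, b) != ARROW:
                continue
            for c in pag.adjacent(b):
                if c == a or pag.has_edge(a, c):
                    continue
                if pag.mark(c, b) == CIRCLE:
                    changed |= pag.set_mark(b, c, ARROW)
                    changed |= pag.set_mark(c, b, TAIL)
    return changed


def _rule2(pag: PAG) -> bool:
    """Chain a -> b *-> c or a *-> b -> c with a *-o c  =>  a *-> c."""
    changed = False
    for a in pag.nodes:
        for c in pag.adjacent(a):
            if pag.mark(a, c) != CIRCLE:
                continue
            for b in pag.adjacent(a):
                if b == c or not pag.has_edge(b, c):
                    continue
                chain1 = pag.is_directed(a, b) and pag.mark(b, c) == ARROW
                chain2 = pag.mark(a, b) == ARROW and pag.is_directed(b, c)
                if chain1 or chain2:
                    changed |= pag.set_mark(a, c, ARROW)
                    break
    return changed


def _rule3(pag: PAG) -> bool:
    """a *-> b <-* c, a *-o d o-* c, a and c non-adjacent, d *-o b  =>  d *-> b."""
    changed = False
    for b in pag.nodes:
        for d in pag.adjacent(b):
            if pag.mark(d, b) != CIRCLE:
                continue
            for a, c in combinations(sorted(pag.adjacent(b)), 2):
                if a == d or c == d or pag.has_edge(a, c):
                    continue
                if pag.mark(a, b) != ARROW or pag.mark(c, b) != ARROW:
                    continue
                if not (pag.has_edge(a, d) and pag.has_edge(c, d)):
                    continue
                if pag.mark(a, d) == CIRCLE and pag.mark(c, d) == CIRCLE:
                    changed |= pag.set_mark(d, b, ARROW)
    return changed


def _discriminating_paths(pag: PAG, b: str, c: str):
    """Yield discriminating paths <theta, ..., a, b, c> for b on edge b-c:
    every vertex strictly between theta and b is a collider on the path
    and a parent of c; theta is non-adjacent to c."""
    for a in pag.adjacent(c):
        if a == b or not pag.has_edge(a, b):
            continue
        # a must be a collider on the path and a parent of c
        if pag.mark(a, b) != ARROW or not pag.is_directed(a, c):
            continue
        # BFS backwards from a, extending with colliders/parents of c
        stack = [[b, a]]
        while stack:
            path = stack.pop()
            tip = path[-1]
            for theta in pag.adjacent(tip):
                if theta in path or theta == c:
                    continue
                if pag.mark(theta, tip) != ARROW:
                    continue
                if not pag.has_edge(theta, c):
                    yield list(reversed(path)) + [c], theta
                elif pag.mark(tip, theta) == ARROW and pag.is_directed(theta, c):
                    stack.append(path + [theta])


def _rule4(pag: PAG, sepsets: SepsetStore) -> bool:
    """Discriminating-path rule: on a discriminating path for b w.r.t.
    c, orient b -> c if b lies in sepset(theta, c), else make a <-> b
    and b <-> c bidirected."""
    changed = False
    for c in pag.nodes:
        for b in pag.adjacent(c):
            if pag.mark(b, c) != CIRCLE and pag.mark(c, b) != CIRCLE:
                continue
            for path, theta in _discriminating_paths(pag, b, c):
                a = path[-3]
                key = frozenset((theta, c))
                if key in sepsets and b in sepsets[key]:
                    changed |= pag.set_mark(b, c, ARROW)
                    changed |= pag.set_mark(c, b, TAIL)
                else:
                    changed |= pag.set_mark(a, b, ARROW)
                    changed |= pag.set_mark(b, a, ARROW)
                    changed |= pag.set_mark(b, c, ARROW)
                    changed |= pag.set_mark(c, b, ARROW)
                if changed:
                    break
    return changed


def apply_orientation_rules(pag: PAG, sepsets: SepsetStore) -> PAG:
    """Apply Zhang's rules R1-R4 to a fixed point (v-structures must
    already be oriented).  Directed consequences of Y-structures
    (a -> b <- c with b - d) emerge from R1.  Marks are monotone: a
    circle may become an arrowhead or a tail, never the reverse."""
    pag = pag.copy()
    limit = max(1, len(pag.edges()) ** 2) * 4
    for _ in range(limit):
        changed = _rule1(pag)
        changed |= _rule2(pag)
        changed |= _rule3(pag)
        changed |= _rule4(pag, sepsets)
        if not changed:
            return pag
    raise RuntimeError("orientation rules failed to reach a fixed point")


# ---------------------------------------------------------------------------
# model facade


class FCIModel:
    """Constraint-based causal discovery over cohort variables.

    Parameters
    ----------
    cohort : cohort to analyse (one row per patient is taken from the
        requested visit; ordinal variables enter the Fisher-z test as
        numeric ranks, a documented approximation).
    variables : variable names to include (cohort covariates and/or
        ``"kl"``).
    family, alpha, max_depth : CI test family and search parameters.
    """

    def __init__(
        self,
        cohort: Cohort,
        variables: list[str],
        family: str = "fisher_z",
        alpha: float = 0.01,
        max_depth: int = 3,
        visit: int | None = 0,
    ):
        missing = [v for v in variables if v not in cohort.data.columns]
        if missing:
            raise ValueError(f"variables absent from cohort: {missing}")
        self.cohort = cohort
        self.variables = sorted(variables)
        self.family = family
        self.alpha = alpha
        self.max_depth = max_depth
        self.visit = visit

    def _matrix(self) -> pd.DataFrame:
        df = self.cohort.data
        if self.visit is not None:
            df = df[df["visit"] == self.visit]
        df = df[self.variables].dropna()
        n_dropped = (len(self.cohort.data if self.visit is None else
                     self.cohort.data[self.cohort.data["visit"] == self.visit])) - len(df)
        if n_dropped:
            logger.info("FCI: dropped %d rows with missing values", n_dropped)
        if len(df) < 50:
            raise ValueError(f"only {len(df)} complete rows; need >= 50")
        if self.family == "fisher_z":
            out = df.copy()
            for v in self.variables:
                sch = self.cohort.schema.get(v)
                if sch is not None and sch.kind in ("ordinal", "binary"):
                    out[v] = rankdata(out[v].to_numpy())
            return out
        return df

    def fit(self) -> "FCIResults":
        data = self._matrix()
        tester = make_tester(data, self.family, self.alpha)
        adj, sepsets = learn_skeleton(
            tester, max_depth=self.max_depth, possible_dsep=True
        )
        pag = orient_v_structures(adj, sepsets)
        pag = apply_orientation_rules(pag, sepsets)
        return FCIResults(self, pag, sepsets, n_used=len(data), n_tests=tester.n_tests)


class FCIResults:
    def __init__(self, model: FCIModel, pag: PAG, sepsets: SepsetStore, n_used: int, n_tests: int):
        self.model = model
        self.pag = pag
        self.sepsets = sepsets
        self.n_used = n_used
        self.n_tests = n_tests

    def summary(self) -> str:
        lines = [
            "FCI partial ancestral graph",
            f"  n = {self.n_used}   CI tests = {self.n_tests}   "
            f"family = {self.model.family}   alpha = {self.model.alpha}",
            "  edges (o undetermined, > arrowhead, - tail):",
        ]
        for _, r in self.pag.to_frame().iterrows():
            left = {"o": "o", ">": "<", "-": "-"}[r.mark_at_source]
            lines.append(f"    {r.source} {left}-{r.mark_at_target} {r.target}")
        return "\n".join(lines)


def run_fci(
    cohort: Cohort,
    variables: list[str],
    family: str = "fisher_z",
    alpha: float = 0.01,
    max_depth: int = 3,
    seed: int = 0,
    visit: int | None = 0,
) -> PAG:
    """Compose skeleton search, v-structure orientation, Possible-D-SEP
    refinement and Zhang's rules into a PAG.  Deterministic given the
    data and parameters (``seed`` is accepted for interface uniformity;
    the procedure involves no randomness)."""
    del seed
    model = FCIModel(cohort, variables, family=family, alpha=alpha,
                     max_depth=max_depth, visit=visit)
    return model.fit().pag
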