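"""CPDAG estimation with the PC algorithm over Gaussian variables.

The PC algorithm learns the Markov equivalence class of a DAG from
conditional-independence (CI) statements, assuming causal sufficiency (no
unmeasured common causes) and faithfulness:

1. *Skeleton*: start from the complete undirected graph; for growing
   conditioning-set sizes, remove the edge i - j as soon as some subset S of
   the (snapshotted) neighborhood renders i and j conditionally independent,
   remembering S as the pair's separating set.  The snapshotting makes the
   skeleton order-independent ("stable" PC).
2. *v-structures*: every unshielded triple x - y - z whose separating set
   does not contain y is oriented as the collider x -> y <- z.
3. *Meek completion*: orientation rules R1-R4 are applied to a fixpoint; the
   result is the completed partially directed acyclic graph (CPDAG), in which
   directed edges are invariant across the equivalence class and undirected
   edges swing between members.

CI testing for Gaussian data uses the Fisher z transform of the partial
correlation: with rho = pcor(i, j | S) estimated from the correlation matrix,
z = atanh(rho) and sqrt(n - |S| - 3) * |z| is approximately standard normal
under the null rho = 0.  The sufficient statistic is therefore just the
correlation matrix and the sample size.

A d-separation oracle over a known DAG exposes the same CI interface, which
lets the whole chain be validated exactly: PC driven by the oracle must
reproduce the true DAG's CPDAG.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import Dag

logger = logging.getLogger(__name__)

_RHO_CLAMP = 1e-7

__all__ = [
    "CiSuffStat",
    "CiTestResult",
    "Cpdag",
    "CpdagSummary",
    "GaussCiTester",
    "partial_correlation",
    "fisher_z_test",
    "pc_skeleton",
    "orient_v_structures",
    "apply_meek_rules",
    "pc",
    "d_separation_oracle",
    "dag_to_cpdag",
    "structural_hamming_distance",
    "summarize_cpdag",
    "suff_stat_from_observations",
    "write_cpdag_tsv",
    "read_cpdag_tsv",
    "cpdag_to_dot",
]


@dataclass(frozen=True)
class CiSuffStat:
    """Sufficient statistic for Gaussian CI tests: correlation matrix + n."""

    correlation: np.ndarray
    n: int
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.correlation, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("correlation must be square")
        if not np.allclose(np.diag(c), 1.0, atol=1e-8):
            raise ValueError("correlation diagonal must be 1")
        if np.abs(c).max() > 1.0 + 1e-8:
            raise ValueError("correlation entries must lie in [-1, 1]")
        if self.n <= 0:
            raise ValueError("sample size must be positive")
        if self.labels and len(self.labels) != c.shape[0]:
            raise ValueError("label count does not match matrix size")
        object.__setattr__(self, "correlation", c)
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"V{i + 1}" for i in range(c.shape[0]))
            )

    @property
    def n_variables(self) -> int:
        return self.correlation.shape[0]


@dataclass(frozen=True)
class CiTestResult:
    partial_correlation: float
    fisher_z: float
    statistic: float
    p_value: float
    independent: bool


def suff_stat_from_observations(
    observations: np.ndarray, labels: Sequence[str] | None = None
) -> CiSuffStat:
    """Build the sufficient statistic from a samples x variables matrix."""
    X = np.asarray(observations, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a samples x variables matrix with >= 2 samples")
    corr = np.clip(np.corrcoef(X, rowvar=False), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CiSuffStat(corr, X.shape[0], tuple(labels) if labels else ())


def partial_correlation(suff: CiSuffStat, i: int, j: int, S: Sequence[int]) -> float:
    """Partial correlation of variables i and j given S, via the inverse of
    the sub-correlation-matrix on {i, j} | S."""
    S = list(S)
    if i == j:
        raise ValueError("i and j must differ")
    if i in S or j in S:
        raise ValueError("conditioning set must exclude i and j")
    idx = [i, j] + S
    sub = suff.correlation[np.ix_(idx, idx)]
    if len(S) == 0:
        rho = float(sub[0, 1])
    else:
        if np.linalg.cond(sub) > 1e12:
            raise np.linalg.LinAlgError(
                f"singular correlation submatrix for ({i}, {j} | {sorted(S)})"
            )
        omega = np.linalg.inv(sub)
        rho = float(-omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1]))
    return float(np.clip(rho, -1.0 + _RHO_CLAMP, 1.0 - _RHO_CLAMP))


def fisher_z_test(
    suff: CiSuffStat, i: int, j: int, S: Sequence[int], alpha: float = 0.05
) -> CiTestResult:
    """Fisher-z test of zero partial correlation at level ``alpha``."""
    dof = suff.n - len(S) - 3
    if dof < 1:
        raise ValueError(
            f"sample size {suff.n} too small for |S| = {len(S)} "
            "(requires n - |S| - 3 >= 1)"
        )
    rho = partial_correlation(suff, i, j, S)
    z = 0.5 * np.log((1.0 + rho) / (1.0 - rho))
    statistic = float(np.sqrt(dof) * abs(z))
    p_value = float(2.0 * (1.0 - sps.norm.cdf(statistic)))
    return CiTestResult(
        partial_correlation=rho,
        fisher_z=float(z),
        statistic=statistic,
        p_value=p_value,
        independent=p_value > alpha,
    )


class CiTester(Protocol):
    """Anything that can answer conditional-independence queries."""

    labels: tuple[str, ...]

    def independent(self, i: int, j: int, S: tuple[int, ...]) -> bool: ...

    def max_cond_size(self) -> int | None: ...


class GaussCiTester:
    """Fisher-z CI tester bound to a sufficient statistic and a level."""

    def __init__(self, suff: CiSuffStat, alpha: float = 0.05):
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        self.suff = suff
        self.alpha = alpha
        self.labels = suff.labels
        self.n_tests = 0

    def independent(self, i: int, j: int, S: tuple[int, ...]) -> bool:
        self.n_tests += 1
        return fisher_z_test(self.suff, i, j, S, self.alpha).independent

    def max_cond_size(self) -> int | None:
        # keeps the Fisher-z precondition n - |S| - 3 >= 1 satisfied with margin
        return max(self.suff.n - 5, 0)


class DSeparationTester:
    """CI oracle answering queries by d-separation in a known DAG."""

    def __init__(self, dag: Dag):
        import networkx as nx

        self.dag = dag
        self.labels = tuple(dag.nodes)
        self._graph = dag.to_networkx()
        self._nx = nx

    def independent(self, i: int, j: int, S: tuple[int, ...]) -> bool:
        names = self.labels
        return bool(
            self._nx.is_d_separator(
                self._graph, {names[i]}, {names[j]}, {names[s] for s in S}
            )
        )

    def max_cond_size(self) -> int | None:
        return None


def d_separation_oracle(dag: Dag) -> DSeparationTester:
    """CI-test interface that is exact for the given DAG."""
    return DSeparationTester(dag)


@dataclass(frozen=True)
class Cpdag:
    """A partially directed graph: directed plus undirected edges."""

    nodes: tuple[str, ...]
    directed_edges: frozenset[tuple[str, str]]
    undirected_edges: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        seen: set[frozenset[str]] = set()
        for a, b in self.directed_edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a}, {b}) uses unknown node")
            pair = frozenset((a, b))
            if pair in seen:
                raise ValueError(f"pair {{{a}, {b}}} appears twice")
            seen.add(pair)
        for pair in self.undirected_edges:
            if len(pair) != 2:
                raise ValueError("undirected edges must join two distinct nodes")
            if not pair <= node_set:
                raise ValueError(f"edge {set(pair)} uses unknown node")
            if pair in seen:
                raise ValueError(f"pair {set(pair)} appears in both edge sets")
            seen.add(pair)

    @property
    def n_edges(self) -> int:
        return len(self.directed_edges) + len(self.undirected_edges)

    def status(self, a: str, b: str) -> str:
        """Edge status of a pair: absent / undirected / '->' / '<-'."""
        if (a, b) in self.directed_edges:
            return "->"
        if (b, a) in self.directed_edges:
            return "<-"
        if frozenset((a, b)) in self.undirected_edges:
            return "--"
        return "absent"


@dataclass(frozen=True)
class CpdagSummary:
    n_directed: int
    n_undirected: int
    n_connected_subgraphs: int
    effect_only_nodes: tuple[str, ...]


SepSetTable = dict[frozenset[str], tuple[str, ...]]


def pc_skeleton(
    suff_or_tester: CiSuffStat | CiTester,
    alpha: float = 0.05,
    max_cond_size: int | None = None,
) -> tuple[dict[str, set[str]], SepSetTable]:
    """Order-independent ("stable") PC skeleton search.

    Returns the adjacency-set representation of the skeleton and the table of
    separating sets recorded when each absent pair's edge was removed.
    """
    tester = _as_tester(suff_or_tester, alpha)
    nodes = list(tester.labels)
    index = {name: k for k, name in enumerate(nodes)}
    adj: dict[str, set[str]] = {v: set(nodes) - {v} for v in nodes}
    sepsets: SepSetTable = {}
    cap = tester.max_cond_size()
    if max_cond_size is not None:
        cap = max_cond_size if cap is None else min(cap, max_cond_size)

    level = 0
    while True:
        if cap is not None and level > cap:
            break
        snapshot = {v: sorted(adj[v], key=index.get) for v in nodes}
        any_testable = False
        for i in nodes:
            for j in snapshot[i]:
                if j not in adj[i]:
                    continue  # already removed at this level
                candidates = [u for u in snapshot[i] if u != j]
                if len(candidates) < level:
                    continue
                any_testable = True
                for S in itertools.combinations(candidates, level):
                    if tester.independent(
                        index[i], index[j], tuple(index[s] for s in S)
                    ):
                        adj[i].discard(j)
                        adj[j].discard(i)
                        sepsets[frozenset((i, j))] = S
                        break
        if not any_testable:
            break
        level += 1
        if all(len(adj[i] - {j}) < level for i in nodes for j in adj[i]):
            break
    # pairs separated trivially before any test (never reached): none, since
    # the search starts complete; every non-adjacent pair has a sepset entry.
    return adj, sepsets


def _as_tester(suff_or_tester: CiSuffStat | CiTester, alpha: float) -> CiTester:
    if isinstance(suff_or_tester, CiSuffStat):
        return GaussCiTester(suff_or_tester, alpha)
    return suff_or_tester


def orient_v_structures(
    skeleton: Mapping[str, set[str]], sepsets: SepSetTable
) -> tuple[set[tuple[str, str]], set[frozenset[str]]]:
    """Orient unshielded colliders x -> y <- z when y is outside sepset(x, z).

    Triples are processed in sorted order; a later triple may overwrite an
    earlier orientation (conflicts are counted and logged).
    """
    nodes = sorted(skeleton)
    orientation: dict[frozenset[str], tuple[str, str] | None] = {}
    for v in nodes:
        for u in skeleton[v]:
            orientation.setdefault(frozenset((u, v)), None)
    conflicts = 0
    for y in nodes:
        for x, z in itertools.combinations(sorted(skeleton[y]), 2):
            if z in skeleton[x]:
                continue  # shielded
            key = frozenset((x, z))
            if key not in sepsets:
                raise KeyError(f"missing separating set for pair {set(key)}")
            if y in sepsets[key]:
                continue
            for tail in (x, z):
                pair = frozenset((tail, y))
                current = orientation[pair]
                if current is not None and current != (tail, y):
                    conflicts += 1
                orientation[pair] = (tail, y)
    if conflicts:
        logger.warning("v-structure orientation conflicts: %d", conflicts)
    directed = {d for d in orientation.values() if d is not None}
    undirected = {p for p, d in orientation.items() if d is None}
    return directed, undirected


def apply_meek_rules(
    nodes: Sequence[str],
    directed: set[tuple[str, str]],
    undirected: set[frozenset[str]],
) -> Cpdag:
    """Meek orientation rules R1-R4 applied to a fixpoint."""
    directed = set(directed)
    undirected = set(undirected)

    def adjacent(a: str, b: str) -> bool:
        return (
            (a, b) in directed
            or (b, a) in directed
            or frozenset((a, b)) in undirected
        )

    def orient(a: str, b: str) -> None:
        undirected.discard(frozenset((a, b)))
        directed.add((a, b))

    changed = True
    while changed:
        changed = False
        for pair in sorted(undirected, key=sorted):
            a, b = sorted(pair)
            for x, y in ((a, b), (b, a)):
                if _meek_fires(x, y, directed, undirected, adjacent):
                    orient(x, y)
                    changed = True
                    break
            if changed:
                break
    node_tuple = tuple(nodes)
    return Cpdag(node_tuple, frozenset(directed), frozenset(undirected))


def _meek_fires(a, b, directed, undirected, adjacent) -> bool:
    """True if some Meek rule orients the undirected edge a - b as a -> b."""
    # R1: c -> a, a - b, c and b non-adjacent  =>  a -> b
    for (c, t) in directed:
        if t == a and c != b and not adjacent(c, b):
            return True
    # R2: a -> c -> b with a - b  =>  a -> b
    for (x, c) in directed:
        if x == a and (c, b) in directed:
            return True
    # R3: a - c, a - d, c -> b, d -> b, c and d non-adjacent  =>  a -> b
    into_b = [c for (c, t) in directed if t == b]
    und_nbrs_a = [
        next(iter(p - {a})) for p in undirected if a in p
    ]
    for c, d in itertools.combinations(sorted(set(into_b) & set(und_nbrs_a)), 2):
        if not adjacent(c, d):
            return True
    # R4: a - c, c -> d, d -> b, c and b non-adjacent, a and d adjacent  =>  a -> b
    for c in und_nbrs_a:
        if adjacent(c, b):
            continue
        for (x, d) in directed:
            if x == c and (d, b) in directed and adjacent(a, d):
                return True
    return False


def pc(
    suff_or_tester: CiSuffStat | CiTester,
    alpha: float = 0.05,
    max_cond_size: int | None = None,
) -> Cpdag:
    """Full PC run: stable skeleton, v-structure orientation, Meek completion."""
    tester = _as_tester(suff_or_tester, alpha)
    skeleton, sepsets = pc_skeleton(tester, alpha, max_cond_size)
    directed, undirected = orient_v_structures(skeleton, sepsets)
    return apply_meek_rules(tuple(tester.labels), directed, undirected)


def dag_to_cpdag(dag: Dag) -> Cpdag:
    """CPDAG of the DAG's Markov equivalence class (skeleton + v-structures,
    then Meek completion)."""
    adjacent_pairs = {frozenset(e) for e in dag.edges}
    directed: set[tuple[str, str]] = set()
    for y in dag.nodes:
        parents = dag.parents(y)
        for x, z in itertools.combinations(sorted(parents), 2):
            if frozenset((x, z)) not in adjacent_pairs:
                directed.add((x, y))
                directed.add((z, y))
    undirected = {
        frozenset(e) for e in dag.edges if (e[0], e[1]) not in directed
    }
    return apply_meek_rules(tuple(dag.nodes), directed, undirected)


def structural_hamming_distance(g1: Cpdag, g2: Cpdag) -> int:
    """Number of node pairs whose edge status (absent / undirected /
    directed either way) differs between the two graphs."""
    if set(g1.nodes) != set(g2.nodes):
        raise ValueError("graphs are defined on different node sets")
    shd = 0
    for a, b in itertools.combinations(sorted(g1.nodes), 2):
        if g1.status(a, b) != g2.status(a, b):
            shd += 1
    return shd


def summarize_cpdag(g: Cpdag) -> CpdagSummary:
    """Edge counts, connected components (>= 2 nodes), and effect-only nodes
    (incoming directed edges only, no outgoing or undirected incidences)."""
    parent: dict[str, str] = {v: v for v in g.nodes}

    def find(v: str) -> str:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    def union(a: str, b: str) -> None:
        parent[find(a)] = find(b)

    for a, b in g.directed_edges:
        union(a, b)
    for pair in g.undirected_edges:
        a, b = tuple(pair)
        union(a, b)
    comp_sizes: dict[str, int] = {}
    for v in g.nodes:
        comp_sizes[find(v)] = comp_sizes.get(find(v), 0) + 1
    n_subgraphs = sum(1 for size in comp_sizes.values() if size >= 2)

    effect_only = []
    for v in g.nodes:
        incoming = sum(1 for (_, t) in g.directed_edges if t == v)
        outgoing = sum(1 for (s, _) in g.directed_edges if s == v)
        und = sum(1 for p in g.undirected_edges if v in p)
        if incoming >= 1 and outgoing == 0 and und == 0:
            effect_only.append(v)
    return CpdagSummary(
        n_directed=len(g.directed_edges),
        n_undirected=len(g.undirected_edges),
        n_connected_subgraphs=n_subgraphs,
        effect_only_nodes=tuple(sorted(effect_only)),
    )


def write_cpdag_tsv(g: Cpdag, path: str | Path) -> None:
    rows = [
        {"source": a, "target": b, "type": "directed"}
        for a, b in sorted(g.directed_edges)
    ]
    rows += [
        {"source": a, "target": b, "type": "undirected"}
        for a, b in sorted(tuple(sorted(p)) for p in g.undirected_edges)
    ]
    pd.DataFrame(rows, columns=["source", "target", "type"]).to_csv(
        path, sep="\t", index=False
    )


def read_cpdag_tsv(path: str | Path, nodes: Sequence[str]) -> Cpdag:
    df = pd.read_csv(path, sep="\t")
    directed = set()
    undirected = set()
    for row in df.itertuples():
        if row.type == "directed":
            directed.add((str(row.source), str(row.target)))
        else:
            undirected.add(frozenset((str(row.source), str(row.target))))
    return Cpdag(tuple(nodes), frozenset(directed), frozenset(undirected))


def cpdag_to_dot(g: Cpdag, name: str = "cpdag") -> str:
    lines = [f"digraph {name} {{"]
    for v in g.nodes:
        lines.append(f'  "{v}";')
    for a, b in sorted(g.directed_edges):
        lines.append(f'  "{a}" -> "{b}";')
    for a, b in sorted(tuple(sorted(p)) for p in g.undirected_edges):
        lines.append(f'  "{a}" -> "{b}" [dir=none];')
    lines.append("}")
    return "\n".join(lines)
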