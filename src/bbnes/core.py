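"""Discrete Bayesian belief networks with exact inference.

A network is a directed acyclic graph over discrete variables ("nodes"),
each with a finite ordered state list and a conditional probability table
(CPT) given its parents.  Posteriors ``P(target | evidence)`` are computed
exactly by variable elimination; the elimination order (min-fill by
default) affects only speed, never the result.

Probabilities are kept in linear space.  Networks of the size this package
targets (tens of nodes, a handful of states each) are nowhere near
underflow; the final normalization step removes any global scale anyway.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "NodeSpec",
    "CPT",
    "Network",
    "Posterior",
    "ImpossibleEvidenceError",
    "validate_network",
    "joint_probability",
    "infer_posterior",
    "infer_joint",
    "prob_evidence",
    "map_state",
    "network_to_dict",
    "network_from_dict",
    "save_network",
    "load_network",
]

#: Evidence is a plain mapping node name -> observed state label.
Evidence = Mapping[str, str]

_ATOL = 1e-9  # tolerance for CPT column normalization


class ImpossibleEvidenceError(ValueError):
    """Raised when the supplied evidence has probability zero."""


@dataclass(frozen=True)
class NodeSpec:
    """A discrete variable: a name, an ordered state list and, for ordered
    variables (e.g. low/medium/high classes), an optional ordinal rank per
    state."""

    name: str
    states: tuple[str, ...]
    ordinal_rank: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 2:
            raise ValueError(f"node {self.name!r} needs >=2 states")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"node {self.name!r} has duplicate state labels")
        if self.ordinal_rank is not None:
            rank = tuple(int(r) for r in self.ordinal_rank)
            object.__setattr__(self, "ordinal_rank", rank)
            if len(rank) != len(self.states) or len(set(rank)) != len(rank):
                raise ValueError(
                    f"node {self.name!r}: ordinal_rank must be a strict total "
                    "order over the states"
                )

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ValueError(
                f"unknown state {state!r} for node {self.name!r}; "
                f"expected one of {list(self.states)}"
            ) from None

    def rank(self, state: str) -> int:
        i = self.index(state)
        return self.ordinal_rank[i] if self.ordinal_rank is not None else i


@dataclass
class CPT:
    """Conditional probability table ``P(child | parents)``.

    ``table`` maps each full parent-state combination (a tuple in declared
    parent order; the empty tuple for root nodes) to a probability vector
    over the child's states.
    """

    child: str
    parents: tuple[str, ...]
    table: dict[tuple[str, ...], np.ndarray]

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        self.table = {
            tuple(k): np.asarray(v, dtype=float) for k, v in self.table.items()
        }

    def column(self, combo: Sequence[str]) -> np.ndarray:
        return self.table[tuple(combo)]


@dataclass
class Posterior:
    """A posterior distribution over one node's states."""

    node: str
    states: tuple[str, ...]
    probabilities: np.ndarray
    evidence: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, state: str) -> float:
        return float(self.probabilities[self.states.index(state)])

    def as_dict(self) -> dict[str, float]:
        return {s: float(p) for s, p in zip(self.states, self.probabilities)}

    def argmax_state(self) -> str:
        # ties broken by declared state order: np.argmax returns the first
        return self.states[int(np.argmax(self.probabilities))]


class Network:
    """A Bayesian network: nodes, arcs and one CPT per node."""

    def __init__(
        self,
        nodes: Iterable[NodeSpec],
        arcs: Iterable[tuple[str, str]],
        cpts: Iterable[CPT] | Mapping[str, CPT] = (),
    ) -> None:
        self.nodes: dict[str, NodeSpec] = {}
        for spec in nodes:
            if spec.name in self.nodes:
                raise ValueError(f"duplicate node {spec.name!r}")
            self.nodes[spec.name] = spec
        self.arcs: list[tuple[str, str]] = [(p, c) for p, c in arcs]
        if isinstance(cpts, Mapping):
            self.cpts = dict(cpts)
        else:
            self.cpts = {cpt.child: cpt for cpt in cpts}

    # -- structure helpers -------------------------------------------------
    def node(self, name: str) -> NodeSpec:
        try:
            return self.nodes[name]
        except KeyError:
            raise ValueError(f"unknown node {name!r}") from None

    def states(self, name: str) -> tuple[str, ...]:
        return self.node(name).states

    def parents(self, name: str) -> tuple[str, ...]:
        return tuple(p for p, c in self.arcs if c == name)

    def children(self, name: str) -> tuple[str, ...]:
        return tuple(c for p, c in self.arcs if p == name)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g

    def copy(self) -> "Network":
        cpts = {
            name: CPT(c.child, c.parents, {k: v.copy() for k, v in c.table.items()})
            for name, c in self.cpts.items()
        }
        return Network(self.nodes.values(), list(self.arcs), cpts)

    def set_cpt(self, cpt: CPT) -> None:
        self.cpts[cpt.child] = cpt

    def check_evidence(self, evidence: Evidence) -> dict[str, str]:
        out = {}
        for name, state in evidence.items():
            self.node(name).index(state)
            out[name] = state
        return out


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_network(net: Network) -> list[str]:
    """Check all structural and numerical invariants.

    Returns a list of human-readable violations; an empty list means the
    network is valid.  Violations are reported, not raised, so a caller can
    present all of them at once.
    """
    violations: list[str] = []
    g = net.graph()
    for p, c in net.arcs:
        for end in (p, c):
            if end not in net.nodes:
                violations.append(f"arc ({p!r}, {c!r}) references unknown node {end!r}")
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        violations.append(
            "cycle: " + " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
        )
    for name, spec in net.nodes.items():
        if name not in net.cpts:
            violations.append(f"node {name!r} has no CPT")
            continue
        cpt = net.cpts[name]
        declared_parents = net.parents(name)
        if tuple(cpt.parents) != declared_parents:
            violations.append(
                f"node {name!r}: CPT parents {list(cpt.parents)} != in-arcs "
                f"{list(declared_parents)}"
            )
            continue
        parent_states = [net.states(p) for p in cpt.parents]
        expected = set(itertools.product(*parent_states)) if parent_states else {()}
        got = set(cpt.table)
        if got != expected:
            missing = expected - got
            extra = got - expected
            if missing:
                violations.append(
                    f"node {name!r}: CPT missing parent combination "
                    f"{sorted(missing)[0]}"
                )
            if extra:
                violations.append(
                    f"node {name!r}: CPT has unexpected parent combination "
                    f"{sorted(extra)[0]}"
                )
            continue
        for combo, col in cpt.table.items():
            if col.shape != (len(spec.states),):
                violations.append(
                    f"node {name!r}, column {combo}: length {col.shape} != "
                    f"{len(spec.states)} states"
                )
                continue
            if np.any(col < -0.0) or np.any(col > 1.0 + _ATOL):
                violations.append(
                    f"node {name!r}, column {combo}: entries outside [0, 1]"
                )
            if abs(float(col.sum()) - 1.0) > _ATOL:
                violations.append(
                    f"node {name!r}, column {combo}: column not normalized "
                    f"(sum={col.sum():.6g})"
                )
    return violations


def require_valid(net: Network) -> None:
    violations = validate_network(net)
    if violations:
        raise ValueError("invalid network: " + "; ".join(violations[:5]))


# ---------------------------------------------------------------------------
# factors and variable elimination
# ---------------------------------------------------------------------------

@dataclass
class _Factor:
    """A nonnegative table over a tuple of variables (axes in order)."""

    vars: tuple[str, ...]
    values: np.ndarray

    def marginalize(self, var: str) -> "_Factor":
        ax = self.vars.index(var)
        return _Factor(
            self.vars[:ax] + self.vars[ax + 1 :], self.values.sum(axis=ax)
        )

    def reduce(self, var: str, index: int) -> "_Factor":
        ax = self.vars.index(var)
        return _Factor(
            self.vars[:ax] + self.vars[ax + 1 :],
            np.take(self.values, index, axis=ax),
        )


def _multiply(a: _Factor, b: _Factor) -> _Factor:
    out_vars = a.vars + tuple(v for v in b.vars if v not in a.vars)
    av = a.values.reshape(a.values.shape + (1,) * (len(out_vars) - len(a.vars)))
    perm = [b.vars.index(v) if v in b.vars else None for v in out_vars]
    b_shape = []
    b_order = [v for v in out_vars if v in b.vars]
    bv = np.transpose(b.values, [b.vars.index(v) for v in b_order])
    it = iter(range(bv.ndim))
    for v in out_vars:
        b_shape.append(bv.shape[next(it)] if v in b.vars else 1)
    bv = bv.reshape(b_shape)
    del perm
    return _Factor(out_vars, av * bv)


def _cpt_factor(net: Network, name: str) -> _Factor:
    cpt = net.cpts[name]
    parent_states = [net.states(p) for p in cpt.parents]
    child_card = len(net.states(name))
    shape = tuple(len(s) for s in parent_states) + (child_card,)
    values = np.empty(shape, dtype=float)
    for combo in itertools.product(*[range(len(s)) for s in parent_states]):
        labels = tuple(parent_states[i][j] for i, j in enumerate(combo))
        values[combo] = cpt.table[labels]
    return _Factor(tuple(cpt.parents) + (name,), values)


def _min_fill_order(factors: list[_Factor], eliminate: set[str]) -> list[str]:
    """Min-fill heuristic on the interaction graph of the factors."""
    neighbors: dict[str, set[str]] = {}
    for f in factors:
        for v in f.vars:
            neighbors.setdefault(v, set()).update(u for u in f.vars if u != v)
    remaining = set(eliminate)
    order = []
    while remaining:
        best, best_fill = None, None
        for v in sorted(remaining):
            nbrs = [u for u in neighbors.get(v, ()) if u != v]
            fill = sum(
                1
                for a, b in itertools.combinations(nbrs, 2)
                if b not in neighbors.get(a, ())
            )
            if best_fill is None or fill < best_fill:
                best, best_fill = v, fill
        order.append(best)
        remaining.discard(best)
        nbrs = neighbors.pop(best, set())
        for u in nbrs:
            neighbors[u].discard(best)
            neighbors[u].update(w for w in nbrs if w != u)
    return order


def _run_elimination(
    factors: list[_Factor],
    keep: Sequence[str],
    to_eliminate: set[str],
    order: Sequence[str] | None = None,
) -> _Factor:
    """Sum ``to_eliminate`` out of the factor product; keep axes in ``keep``."""
    if order is None:
        order = _min_fill_order(factors, to_eliminate)
    elif set(order) != to_eliminate:
        raise ValueError(
            "elimination order must cover exactly the summed-out variables"
        )
    for var in order:
        involved = [f for f in factors if var in f.vars]
        rest = [f for f in factors if var not in f.vars]
        if not involved:
            continue
        prod = involved[0]
        for f in involved[1:]:
            prod = _multiply(prod, f)
        factors = rest + [prod.marginalize(var)]
    if not factors:
        return _Factor((), np.array(1.0))
    prod = factors[0]
    for f in factors[1:]:
        prod = _multiply(prod, f)
    # collapse any evidence-free scalar axes and order axes as in `keep`
    for v in prod.vars:
        if v not in keep:  # pragma: no cover - all kept by construction
            prod = prod.marginalize(v)
    if tuple(prod.vars) != tuple(keep):
        perm = [prod.vars.index(v) for v in keep]
        prod = _Factor(tuple(keep), np.transpose(prod.values, perm))
    return prod


def _reduce_by_evidence(
    net: Network, factors: list[_Factor], evidence: Evidence
) -> list[_Factor]:
    for var, state in evidence.items():
        idx = net.node(var).index(state)
        factors = [f.reduce(var, idx) if var in f.vars else f for f in factors]
    return factors


def _eliminate(
    net: Network,
    keep: Sequence[str],
    evidence: Evidence,
    order: Sequence[str] | None = None,
    factors: list[_Factor] | None = None,
) -> _Factor:
    """Sum out every variable not kept and not evidenced.

    Returns the unnormalized factor over ``keep`` (evidence variables are
    reduced out; their probability mass is absorbed into the scale).
    ``factors`` lets a caller reuse prebuilt CPT factors.
    """
    evidence = net.check_evidence(evidence)
    if factors is None:
        factors = [_cpt_factor(net, n) for n in net.nodes]
    factors = _reduce_by_evidence(net, factors, evidence)
    to_eliminate = set(net.nodes) - set(keep) - set(evidence)
    return _run_elimination(factors, keep, to_eliminate, order)


def prob_evidence(net: Network, evidence: Evidence) -> float:
    """Marginal probability of the evidence, ``P(e)``."""
    f = _eliminate(net, (), evidence)
    return float(f.values)


def infer_joint(
    net: Network,
    targets: Sequence[str],
    evidence: Evidence | None = None,
    order: Sequence[str] | None = None,
    normalize: bool = True,
) -> _Factor:
    """Exact joint posterior over ``targets`` given ``evidence``.

    Targets that are themselves evidenced come back as point masses.
    """
    evidence = dict(evidence or {})
    targets = list(targets)
    free = [t for t in targets if t not in evidence]
    f = _eliminate(net, free, evidence, order=order)
    total = float(f.values.sum())
    if total <= 0.0:
        raise ImpossibleEvidenceError(
            f"evidence {evidence!r} has probability 0 under the network"
        )
    values = f.values / total if normalize else f.values
    out = _Factor(tuple(free), values)
    # re-insert evidenced targets as point-mass axes, in requested order
    for t in targets:
        if t in evidence and t not in out.vars:
            card = len(net.states(t))
            point = np.zeros(card)
            point[net.node(t).index(evidence[t])] = 1.0
            out = _multiply(out, _Factor((t,), point))
    if tuple(out.vars) != tuple(targets):
        perm = [out.vars.index(v) for v in targets]
        out = _Factor(tuple(targets), np.transpose(out.values, perm))
    return out


def infer_posterior(
    net: Network,
    targets: str | Sequence[str],
    evidence: Evidence | None = None,
    order: Sequence[str] | None = None,
) -> dict[str, Posterior]:
    """Exact marginal posterior of each target node given evidence.

    With empty evidence this returns the prior marginals.  Zero-probability
    evidence raises :class:`ImpossibleEvidenceError`.
    """
    if isinstance(targets, str):
        targets = [targets]
    evidence = dict(evidence or {})
    out: dict[str, Posterior] = {}
    for t in targets:
        f = infer_joint(net, [t], evidence, order=order)
        out[t] = Posterior(t, net.states(t), f.values, dict(evidence))
    return out


def joint_probability(net: Network, assignment: Mapping[str, str]) -> float:
    """Probability of one full assignment: the product over nodes of the CPT
    entry selected by the assignment."""
    missing = set(net.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment missing nodes: {sorted(missing)}")
    prob = 1.0
    for name, spec in net.nodes.items():
        cpt = net.cpts[name]
        combo = tuple(assignment[p] for p in cpt.parents)
        for p, s in zip(cpt.parents, combo):
            net.node(p).index(s)
        prob *= float(cpt.column(combo)[spec.index(assignment[name])])
    return prob


def map_state(net: Network, node: str, evidence: Evidence | None = None) -> str:
    """Maximum a-posteriori state of ``node`` given evidence; ties go to the
    first state in declared order."""
    evidence = dict(evidence or {})
    if node in evidence:
        net.node(node).index(evidence[node])
        return evidence[node]
    return infer_posterior(net, node, evidence)[node].argmax_state()


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def network_to_dict(net: Network) -> dict:
    nodes = []
    for spec in net.nodes.values():
        d: dict = {"name": spec.name, "states": list(spec.states)}
        if spec.ordinal_rank is not None:
            d["ordinal_rank"] = list(spec.ordinal_rank)
        nodes.append(d)
    cpts = {}
    for name, cpt in net.cpts.items():
        cpts[name] = {
            "parents": list(cpt.parents),
            "table": {
                "|".join(combo): [float(x) for x in col]
                for combo, col in cpt.table.items()
            },
        }
    return {"nodes": nodes, "arcs": [list(a) for a in net.arcs], "cpts": cpts}


def network_from_dict(doc: Mapping) -> Network:
    nodes = [
        NodeSpec(
            d["name"],
            tuple(d["states"]),
            tuple(d["ordinal_rank"]) if d.get("ordinal_rank") is not None else None,
        )
        for d in doc["nodes"]
    ]
    arcs = [tuple(a) for a in doc["arcs"]]
    cpts = {}
    for child, entry in doc.get("cpts", {}).items():
        parents = tuple(entry["parents"])
        table = {}
        for key, col in entry["table"].items():
            combo = tuple(key.split("|")) if key else ()
            table[combo] = np.asarray(col, dtype=float)
        cpts[child] = CPT(child, parents, table)
    return Network(nodes, arcs, cpts)


def save_network(net: Network, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net), fh, indent=1)


def load_network(path) -> Network:
    with open(path) as fh:
        return network_from_dict(json.load(fh))
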