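"""Model-interrogation procedures: evidence scenarios, arc strength,
posterior sensitivity analysis and k-fold cross-validation.

Arc strength is the mutual information (in bits) between the arc's two
endpoints under the network's joint distribution — symmetric, nonnegative
and zero exactly at independence, matching the intuition behind drawing
influential arcs wider.

The sensitivity analysis differentiates each posterior of a target node
with respect to every CPT entry, co-varying the remaining entries of the
perturbed column proportionally so it stays normalized.  Under that
one-parameter perturbation every posterior is a ratio of two affine
functions of the parameter, so the derivative is computed analytically
from two exact inference evaluations; parameters of nodes that are
d-separation-irrelevant for the target are exactly zero by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .core import (
    CPT,
    Evidence,
    Network,
    Posterior,
    _cpt_factor,
    _eliminate,
    infer_joint,
    infer_posterior,
)
from .learning import LearningConfig, learn_cpts
from .model import StateRecord

__all__ = [
    "arc_strength",
    "ParamSensitivity",
    "SensitivityReport",
    "sensitivity_analysis",
    "finite_difference_derivatives",
    "CVResult",
    "kfold_cv",
    "ScenarioTable",
    "scenario_compare",
]


# ---------------------------------------------------------------------------
# arc strength
# ---------------------------------------------------------------------------

def arc_strength(net: Network, arc: tuple[str, str]) -> float:
    """Mutual information I(parent; child) in bits under the joint."""
    parent, child = arc
    if tuple(arc) not in {tuple(a) for a in net.arcs}:
        raise ValueError(f"arc {arc!r} is not in the network")
    joint = infer_joint(net, [parent, child]).values
    pi = joint.sum(axis=1)
    pj = joint.sum(axis=0)
    mask = joint > 0
    outer = np.outer(pi, pj)
    mi = float(np.sum(joint[mask] * np.log2(joint[mask] / outer[mask])))
    return max(mi, 0.0)  # clip -0.0 / rounding at exact independence


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class ParamSensitivity:
    """Derivatives of the target posteriors w.r.t. one CPT entry."""

    node: str
    parent_combo: tuple[str, ...]
    child_state: str
    theta: float
    derivatives: np.ndarray  # d P(target=state | e) / d theta, per target state


@dataclass
class SensitivityReport:
    target: str
    target_states: tuple[str, ...]
    evidence: dict[str, str]
    entries: list[ParamSensitivity]
    node_aggregate: dict[str, float] = field(default_factory=dict)
    ranking: list[tuple[str, float]] = field(default_factory=list)

    def finalize(self) -> "SensitivityReport":
        agg: dict[str, float] = {}
        for e in self.entries:
            m = float(np.max(np.abs(e.derivatives)))
            agg[e.node] = max(agg.get(e.node, 0.0), m)
        self.node_aggregate = agg
        self.ranking = sorted(agg.items(), key=lambda kv: (-kv[1], kv[0]))
        return self


def _covaried_column(col: np.ndarray, i: int, t: float) -> np.ndarray:
    """Set entry i to t; rescale the rest proportionally (uniformly when the
    original remaining mass is zero) so the column still sums to 1."""
    out = np.array(col, dtype=float)
    rest = 1.0 - col[i]
    out[i] = t
    others = np.arange(len(col)) != i
    if rest > 0:
        out[others] = col[others] * (1.0 - t) / rest
    else:
        out[others] = (1.0 - t) / max(len(col) - 1, 1)
    return out


def _relevant_nodes(net: Network, target: str, evidence: Evidence) -> set[str]:
    """Nodes whose CPT entries can move the target posterior.

    A node X is irrelevant when an auxiliary parameter-parent of X would be
    d-separated from the target given the evidence; its derivatives are
    exactly zero.
    """
    g = net.graph()
    z = set(evidence)
    relevant = set()
    for x in net.nodes:
        aux = "__theta__"
        g.add_edge(aux, x)
        if not nx.is_d_separator(g, {aux}, {target}, z - {aux}):
            relevant.add(x)
        g.remove_node(aux)
    return relevant


def sensitivity_analysis(
    net: Network,
    target: str,
    evidence: Evidence | None = None,
    nodes: Sequence[str] | None = None,
) -> SensitivityReport:
    """Differentiate the target posteriors w.r.t. every CPT entry.

    Under proportional covariation both the unnormalized posterior mass
    N_s(t) = P(target=s, e) and its normalizer D(t) = P(e) are affine in
    the perturbed entry t, so two evaluations (t=0, t=1) determine the
    exact derivative d/dt [N_s/D] at the entry's current value.
    """
    evidence = dict(evidence or {})
    net.check_evidence(evidence)
    if target in evidence:
        raise ValueError(f"target {target!r} must not be part of the evidence")
    states = net.states(target)
    base_factors = {name: _cpt_factor(net, name) for name in net.nodes}
    relevant = _relevant_nodes(net, target, evidence)
    node_list = list(nodes) if nodes is not None else list(net.nodes)

    def posterior_mass(node: str, combo: tuple[str, ...], i: int, t: float) -> tuple[np.ndarray, float]:
        trial = net.copy()
        col = net.cpts[node].column(combo)
        trial.cpts[node].table[combo] = _covaried_column(col, i, t)
        factors = dict(base_factors)
        factors[node] = _cpt_factor(trial, node)
        f = _eliminate(net, (target,), evidence, factors=list(factors.values()))
        n = f.values.astype(float)
        return n, float(n.sum())

    entries: list[ParamSensitivity] = []
    for node in node_list:
        cpt = net.cpts[node]
        k = len(net.states(node))
        for combo, col in cpt.table.items():
            for i in range(k):
                theta = float(col[i])
                if node not in relevant:
                    deriv = np.zeros(len(states))
                else:
                    n0, d0 = posterior_mass(node, combo, i, 0.0)
                    n1, d1 = posterior_mass(node, combo, i, 1.0)
                    a1 = n1 - n0  # slope of N_s(t)
                    b1 = d1 - d0  # slope of D(t)
                    n_at = n0 + a1 * theta
                    d_at = d0 + b1 * theta
                    if d_at <= 0:
                        raise ValueError(
                            "evidence has probability 0 at the current parameters"
                        )
                    deriv = (a1 * d_at - n_at * b1) / (d_at * d_at)
                entries.append(
                    ParamSensitivity(node, combo, net.states(node)[i], theta, deriv)
                )
    return SensitivityReport(target, states, evidence, entries).finalize()


def finite_difference_derivatives(
    net: Network,
    target: str,
    evidence: Evidence | None = None,
    node: str | None = None,
    combo: tuple[str, ...] | None = None,
    state_index: int = 0,
    h: float = 1e-4,
) -> np.ndarray:
    """Central finite-difference check of one parameter's derivatives.

    Steps the entry by ±h under the same proportional covariation and
    re-runs exact inference; independent of the analytic path.
    """
    evidence = dict(evidence or {})
    col = net.cpts[node].column(combo)
    theta = float(col[state_index])

    def at(t: float) -> np.ndarray:
        trial = net.copy()
        trial.cpts[node].table[tuple(combo)] = _covaried_column(col, state_index, t)
        return infer_posterior(trial, target, evidence)[target].probabilities

    lo, hi = theta - h, theta + h
    if lo < 0.0:
        lo = 0.0
    if hi > 1.0:
        hi = 1.0
    return (at(hi) - at(lo)) / (hi - lo)


# ---------------------------------------------------------------------------
# k-fold cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    k: int
    node: str
    seed: int
    fold_sizes: list[int]
    fold_accuracy: list[float]
    fold_logloss: list[float]
    accuracy: float = 0.0
    logloss: float = 0.0

    def __post_init__(self) -> None:
        self.accuracy = float(np.mean(self.fold_accuracy))
        self.logloss = float(np.mean(self.fold_logloss))


def kfold_cv(
    structure: Network,
    records: Sequence[StateRecord],
    k: int,
    node: str,
    cfg: LearningConfig | None = None,
    seed: int = 0,
) -> CVResult:
    """k-fold cross-validated prediction of one node.

    The records are shuffled with the given seed and split into k
    near-equal folds; for each fold the CPTs are learned on the remaining
    k-1 folds and the held-out records are predicted by the MAP state of
    ``node`` given every other variable the record observes.  Per-fold
    accuracy and mean log-loss are reported together with their averages.
    """
    n = len(records)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of records ({n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    cfg = cfg or LearningConfig()
    fold_sizes, fold_acc, fold_ll = [], [], []
    for held in folds:
        held_set = set(int(i) for i in held)
        train = [records[i] for i in range(n) if i not in held_set]
        net = learn_cpts(structure, train, cfg)
        cache: dict[tuple, Posterior] = {}
        correct, losses = 0, []
        for i in held:
            rec = records[int(i)]
            ev = {v: s for v, s in rec.items() if v != node}
            key = tuple(sorted(ev.items()))
            if key not in cache:
                cache[key] = infer_posterior(net, node, ev)[node]
            post = cache[key]
            if post.argmax_state() == rec[node]:
                correct += 1
            p = max(post[rec[node]], 1e-300)
            losses.append(-math.log(p))
        fold_sizes.append(len(held))
        fold_acc.append(correct / len(held))
        fold_ll.append(float(np.mean(losses)))
    return CVResult(k, node, seed, fold_sizes, fold_acc, fold_ll)


# ---------------------------------------------------------------------------
# evidence scenarios
# ---------------------------------------------------------------------------

@dataclass
class ScenarioTable:
    """Posteriors of the queried nodes under each evidence scenario, always
    including the empty-evidence baseline, plus arc strengths."""

    scenarios: list[tuple[str, dict[str, str]]]
    query: list[str]
    posteriors: dict[str, dict[str, Posterior]]  # label -> node -> posterior
    arc_strengths: dict[tuple[str, str], float]


def scenario_compare(
    net: Network,
    scenarios: Sequence[tuple[str, Mapping[str, str]]],
    query: Sequence[str],
) -> ScenarioTable:
    """Posterior of each queried node per scenario plus the baseline."""
    all_scenarios: list[tuple[str, dict[str, str]]] = [("baseline", {})]
    all_scenarios += [(label, dict(ev)) for label, ev in scenarios]
    posteriors: dict[str, dict[str, Posterior]] = {}
    for label, ev in all_scenarios:
        posteriors[label] = infer_posterior(net, list(query), ev)
    strengths = {tuple(a): arc_strength(net, tuple(a)) for a in net.arcs}
    return ScenarioTable(all_scenarios, list(query), posteriors, strengths)
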