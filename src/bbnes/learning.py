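"""Maximum-likelihood CPT estimation from discretized grid records.

Counts parent/child state co-occurrences over the (complete-case) records
and normalizes with an optional Dirichlet pseudocount:

    P(child=s | parents=p) = (count(s, p) + alpha) / (count(p) + alpha * K)

with K the number of child states.  ``alpha=0`` is the plain MLE and
refuses unobserved parent combinations; the pipeline default ``alpha=1``
(Laplace) keeps sparse strata — e.g. a landscape type absent from a study
area — well-defined.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import CPT, Network, prob_evidence
from .model import OBSERVED_NODES, StateRecord

__all__ = ["LearningConfig", "learn_cpts", "loglikelihood"]


@dataclass(frozen=True)
class LearningConfig:
    """How CPTs are estimated.

    alpha: Dirichlet pseudocount added to every child-state cell.
    nodes: the nodes to (re-)learn; defaults to the model's observed nodes.
    missing_policy: 'complete-case' drops records missing any needed
    variable; 'error' refuses them.
    """

    alpha: float = 1.0
    nodes: tuple[str, ...] = OBSERVED_NODES
    missing_policy: str = "complete-case"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and self.alpha >= 0):
            raise ValueError(f"alpha must be finite and >= 0, got {self.alpha!r}")
        if self.missing_policy not in ("complete-case", "error"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")


def _check_record(net: Network, rec: StateRecord) -> None:
    for node, state in rec.items():
        net.node(node).index(state)


def learn_cpts(
    net: Network,
    records: Sequence[StateRecord],
    cfg: LearningConfig | None = None,
) -> Network:
    """Return a copy of ``net`` with the configured nodes' CPTs re-estimated.

    Expert/untouched nodes keep their CPTs.  With ``alpha=0`` an unobserved
    parent combination is an error; with ``alpha>0`` it yields a uniform
    column.
    """
    cfg = cfg or LearningConfig()
    if not records:
        raise ValueError("cannot learn CPTs from an empty record set")
    out = net.copy()
    for node in cfg.nodes:
        parents = out.parents(node)
        needed = (node, *parents)
        rows = []
        for i, rec in enumerate(records):
            if any(v not in rec for v in needed):
                if cfg.missing_policy == "error":
                    raise ValueError(
                        f"record {i} is missing a value needed to learn {node!r}"
                    )
                continue
            rows.append(rec)
        child_states = out.states(node)
        k = len(child_states)
        counts: dict[tuple[str, ...], np.ndarray] = {
            combo: np.zeros(k)
            for combo in itertools.product(*[out.states(p) for p in parents])
        }
        for rec in rows:
            _check_record(out, {v: rec[v] for v in needed})
            combo = tuple(rec[p] for p in parents)
            counts[combo][child_states.index(rec[node])] += 1
        table = {}
        for combo, cnt in counts.items():
            total = cnt.sum()
            if total == 0 and cfg.alpha == 0:
                raise ValueError(
                    f"node {node!r}: parent combination {combo} never observed "
                    "and alpha=0 (no pseudocounts) — cannot estimate the column"
                )
            table[combo] = (cnt + cfg.alpha) / (total + cfg.alpha * k)
        out.set_cpt(CPT(node, parents, table))
    return out


def loglikelihood(
    net: Network,
    records: Iterable[StateRecord],
    strict: bool = True,
) -> float:
    """Total log-likelihood of the records under the network.

    Each record's contribution is ``log P(observed values)``, marginalizing
    any node the record does not mention through exact inference.  A record
    with probability zero raises under ``strict`` and is skipped otherwise.
    """
    total = 0.0
    for i, rec in enumerate(records):
        _check_record(net, rec)
        p = prob_evidence(net, rec)
        if p <= 0.0:
            if strict:
                raise ValueError(f"record {i} has probability 0 under the network")
            continue
        total += math.log(p)
    return total
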