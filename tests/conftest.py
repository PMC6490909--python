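"""Shared fixtures: small hand-built networks, a seeded random-network
factory, and an independent full-joint enumeration oracle for posteriors.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from bbnes.core import CPT, Network, NodeSpec
from bbnes.learning import LearningConfig, learn_cpts
from bbnes.model import build_network, default_scheme, discretize_record
from bbnes.synthetic import default_generator_config, generate_grid


# ---------------------------------------------------------------------------
# independent oracle: posteriors by brute-force enumeration of the joint
# ---------------------------------------------------------------------------

def full_joint_tensor(net: Network) -> tuple[list[str], np.ndarray]:
    """The joint distribution as a dense tensor, built by plain broadcasting
    over all CPTs — no factor algebra, no elimination."""
    order = list(net.nodes)
    shape = tuple(len(net.states(v)) for v in order)
    joint = np.ones(shape)
    for name in order:
        cpt = net.cpts[name]
        axes = [order.index(p) for p in cpt.parents] + [order.index(name)]
        block = np.empty(tuple(shape[a] for a in axes))
        parent_states = [net.states(p) for p in cpt.parents]
        for combo_idx in itertools.product(*[range(len(s)) for s in parent_states]):
            labels = tuple(parent_states[i][j] for i, j in enumerate(combo_idx))
            block[combo_idx] = cpt.table[labels]
        joint = joint * _expand(block, axes, len(order))
    return order, joint


def _expand(block: np.ndarray, axes: list[int], ndim: int) -> np.ndarray:
    perm = np.argsort(axes)
    block = np.transpose(block, perm)
    idx = [np.newaxis] * ndim
    for a in sorted(axes):
        idx[a] = slice(None)
    return block[tuple(idx)]


def enumerate_posterior(
    net: Network, target: str, evidence: dict[str, str] | None = None
) -> np.ndarray:
    """P(target | evidence) by conditioning and summing the full joint."""
    evidence = evidence or {}
    order, joint = full_joint_tensor(net)
    for var, state in evidence.items():
        i = order.index(var)
        mask = np.zeros(joint.shape[i])
        mask[net.node(var).index(state)] = 1.0
        joint = joint * _expand(mask, [i], joint.ndim)
    keep = order.index(target)
    summed = joint.sum(axis=tuple(i for i in range(joint.ndim) if i != keep))
    total = summed.sum()
    if total == 0:
        raise ZeroDivisionError("evidence probability zero")
    return summed / total


# ---------------------------------------------------------------------------
# random acyclic networks
# ---------------------------------------------------------------------------

def random_network(
    seed: int, max_nodes: int = 8, max_states: int = 4, max_parents: int = 3
) -> Network:
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"X{i}" for i in range(n)]
    specs, arcs, cpts = [], [], []
    for i, name in enumerate(names):
        card = int(rng.integers(2, max_states + 1))
        states = tuple(f"s{j}" for j in range(card))
        specs.append(NodeSpec(name, states))
        k = int(rng.integers(0, min(i, max_parents) + 1))
        parents = tuple(
            names[j] for j in sorted(rng.choice(i, size=k, replace=False))
        ) if k else ()
        arcs += [(p, name) for p in parents]
        parent_cards = [len(specs[names.index(p)].states) for p in parents]
        table = {}
        for combo in itertools.product(
            *[specs[names.index(p)].states for p in parents]
        ):
            table[combo] = rng.dirichlet(np.ones(card))
        cpts.append(CPT(name, parents, table))
        del parent_cards
    return Network(specs, arcs, cpts)


def random_evidence(net: Network, seed: int) -> dict[str, str]:
    rng = np.random.default_rng(seed + 10_000)
    names = list(net.nodes)
    k = int(rng.integers(0, max(1, len(names) // 2) + 1))
    chosen = rng.choice(len(names), size=k, replace=False)
    return {
        names[i]: net.states(names[i])[int(rng.integers(len(net.states(names[i]))))]
        for i in chosen
    }


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def two_node_net() -> Network:
    """A -> B with P(a1)=0.3, P(b1|a1)=0.8, P(b1|a2)=0.2."""
    return Network(
        [NodeSpec("A", ("a1", "a2")), NodeSpec("B", ("b1", "b2"))],
        [("A", "B")],
        [
            CPT("A", (), {(): np.array([0.3, 0.7])}),
            CPT(
                "B",
                ("A",),
                {("a1",): np.array([0.8, 0.2]), ("a2",): np.array([0.2, 0.8])},
            ),
        ],
    )


@pytest.fixture
def uniform_chain3() -> Network:
    """A -> B -> C, every CPT entry 0.5."""
    half = np.array([0.5, 0.5])
    return Network(
        [NodeSpec(v, ("0", "1")) for v in "ABC"],
        [("A", "B"), ("B", "C")],
        [
            CPT("A", (), {(): half}),
            CPT("B", ("A",), {("0",): half, ("1",): half}),
            CPT("C", ("B",), {("0",): half, ("1",): half}),
        ],
    )


@pytest.fixture(scope="session")
def sh_learned():
    """Default Schleswig-Holstein generator -> discretize -> learn (alpha=1)."""
    gen = default_generator_config("schleswig-holstein", n_cells=4000, seed=3)
    grid = generate_grid(gen)
    scheme = default_scheme()
    matrix = gen.es_matrix()
    records = [discretize_record(r, scheme, matrix) for r in grid]
    net = learn_cpts(build_network(), records, LearningConfig(alpha=1.0))
    return gen, grid, records, net
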