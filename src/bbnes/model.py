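"""The 14-node nutrient-regulation model.

The network relates the three Schleswig-Holstein landscape types
(Hügelland, Geest, Marsch) and site-specific environmental variables
(soil texture, slope, field capacity, natural nutrient availability,
nitrate leaching, wind/water erosion) to the nutrient-regulation
ecosystem-service (ES) potential of a grid cell, the demand for the
service (indexed by the nitrogen surplus of the cell), and their balance
(the ES "budget": sustainable when the reclassified potential is at least
as high as the demand).

Ten nodes are observed on the landscape grid and their CPTs are learned
from data (:mod:`bbnes.learning`); four nodes — overall erosion, the
nutrient-regulation ES potential, its low/medium/high reclassification
and the budget — carry expert-style CPTs generated here from documented
heuristics (:func:`default_expert_cpt`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field as dataclass_field
from typing import Mapping, Sequence

import numpy as np

from .core import CPT, Network, NodeSpec

__all__ = [
    "NODE_ORDER",
    "OBSERVED_NODES",
    "EXPERT_NODES",
    "DEFAULT_ARCS",
    "POTENTIAL_STATES",
    "Interval",
    "DiscretizationScheme",
    "ESMatrixTable",
    "GridRecord",
    "StateRecord",
    "ExpertCPTParams",
    "build_network",
    "default_scheme",
    "discretize_record",
    "quantile_breaks",
    "lookup_preliminary_potential",
    "reclassify_potential",
    "budget_state",
    "default_expert_cpt",
]

POTENTIAL_STATES = ("P_no", "P_1", "P_2", "P_3", "P_4", "P_5")

#: node name -> ordered state labels
NODE_STATES: dict[str, tuple[str, ...]] = {
    "landscape_type": ("huegelland", "geest", "marsch"),
    "soil_texture": ("sand", "peat", "silt_clay", "other"),
    "slope": ("low", "medium", "high"),
    "field_capacity": ("low", "medium", "high"),
    "wind_erosion": ("no", "low", "medium", "high"),
    "water_erosion": ("no", "low", "medium", "high"),
    "natural_nutrient_availability": ("low", "medium", "high"),
    "nitrate_leaching_potential": ("low", "medium", "high"),
    "erosion": ("low", "medium", "high"),
    "preliminary_potential": POTENTIAL_STATES,
    "nutrient_regulation_potential": POTENTIAL_STATES,
    "reclassified_potential": ("low", "medium", "high"),
    "demand": ("low", "medium", "high"),
    "budget": ("sustainable", "unsustainable"),
}

NODE_ORDER = tuple(NODE_STATES)

#: nodes whose states are read off the grid data (training columns)
OBSERVED_NODES = (
    "landscape_type",
    "soil_texture",
    "slope",
    "field_capacity",
    "wind_erosion",
    "water_erosion",
    "natural_nutrient_availability",
    "nitrate_leaching_potential",
    "preliminary_potential",
    "demand",
)

#: nodes with expert-style CPTs (not derivable from the grid columns)
EXPERT_NODES = (
    "erosion",
    "nutrient_regulation_potential",
    "reclassified_potential",
    "budget",
)

DEFAULT_ARCS: tuple[tuple[str, str], ...] = (
    ("landscape_type", "soil_texture"),
    ("landscape_type", "slope"),
    ("landscape_type", "preliminary_potential"),
    ("landscape_type", "demand"),
    ("soil_texture", "field_capacity"),
    ("soil_texture", "natural_nutrient_availability"),
    ("soil_texture", "nitrate_leaching_potential"),
    ("soil_texture", "wind_erosion"),
    ("slope", "water_erosion"),
    ("wind_erosion", "erosion"),
    ("water_erosion", "erosion"),
    ("field_capacity", "nutrient_regulation_potential"),
    ("natural_nutrient_availability", "nutrient_regulation_potential"),
    ("nitrate_leaching_potential", "nutrient_regulation_potential"),
    ("erosion", "nutrient_regulation_potential"),
    ("preliminary_potential", "nutrient_regulation_potential"),
    ("nutrient_regulation_potential", "reclassified_potential"),
    ("reclassified_potential", "budget"),
    ("demand", "budget"),
)

_LMH_RANK = {"low": 0, "medium": 1, "high": 2}


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    """Half-open/closed numeric interval with explicit boundary ownership."""

    lo: float
    hi: float
    lo_closed: bool
    hi_closed: bool

    def __contains__(self, x: float) -> bool:
        above = x > self.lo or (self.lo_closed and x == self.lo)
        below = x < self.hi or (self.hi_closed and x == self.hi)
        return above and below


def _bands(
    breaks: Sequence[float],
    labels: Sequence[str],
    first_lo: float = 0.0,
    closure: str = "right",
) -> tuple[tuple[str, Interval], ...]:
    """Build len(breaks)+1 contiguous intervals.

    ``closure='right'``: (lo, b1], (b1, b2], ... — each break belongs to the
    band below it.  ``closure='left'``: [lo, b1), [b1, b2] ... — used for the
    "<200 / 200-300 / >300" reading where the printed range owns both of its
    boundary values.
    """
    edges = [first_lo, *breaks, math.inf]
    out = []
    for i, lab in enumerate(labels):
        lo, hi = edges[i], edges[i + 1]
        if closure == "right":
            out.append((lab, Interval(lo, hi, lo_closed=(i == 0), hi_closed=hi != math.inf)))
        else:  # closed middle band: [0, b1) / [b1, b2] / (b2, inf)
            if i == 0:
                out.append((lab, Interval(lo, hi, True, False)))
            elif i == len(labels) - 1:
                out.append((lab, Interval(lo, hi, False, False)))
            else:
                out.append((lab, Interval(lo, hi, True, True)))
    return tuple(out)


@dataclass(frozen=True)
class DiscretizationScheme:
    """Class boundaries for the continuous grid variables.

    Defaults encode the model's standard class limits: field capacity
    <200 / 200-300 / >300 mm; natural nutrient availability <300 / 300-600 /
    >600 kmol_c/ha; nitrogen surplus (the demand indicator) <=40 / 41-60 /
    >60 kg N/ha; slope classified at the quantile breaks 0.2039 and 0.6581
    degrees.  Each boundary value belongs to exactly one class: the
    printed "200-300" style ranges own both of their endpoints, the
    surplus and slope bands are closed on the right.
    """

    field_capacity: tuple[tuple[str, Interval], ...] = _bands(
        (200.0, 300.0), ("low", "medium", "high"), closure="left"
    )
    natural_nutrient_availability: tuple[tuple[str, Interval], ...] = _bands(
        (300.0, 600.0), ("low", "medium", "high"), closure="left"
    )
    nitrogen_surplus: tuple[tuple[str, Interval], ...] = _bands(
        (40.0, 60.0), ("low", "medium", "high"), first_lo=-math.inf, closure="right"
    )
    slope: tuple[tuple[str, Interval], ...] = _bands(
        (0.2039, 0.6581), ("low", "medium", "high"), closure="right"
    )

    def classify(self, variable: str, value: float) -> str:
        bands = getattr(self, variable)
        for label, interval in bands:
            if value in interval:
                return label
        raise ValueError(
            f"{variable} value {value!r} falls outside every declared interval"
        )

    def with_slope_breaks(self, b1: float, b2: float) -> "DiscretizationScheme":
        """Scheme with slope class breaks replaced (e.g. by data quantiles)."""
        return DiscretizationScheme(
            field_capacity=self.field_capacity,
            natural_nutrient_availability=self.natural_nutrient_availability,
            nitrogen_surplus=self.nitrogen_surplus,
            slope=_bands((b1, b2), ("low", "medium", "high"), closure="right"),
        )


def default_scheme() -> DiscretizationScheme:
    return DiscretizationScheme()


def quantile_breaks(values: Sequence[float], n_classes: int) -> tuple[float, ...]:
    """Class breaks for an n-class quantile classification.

    The k-th break (k = 1..n_classes-1) is the ceil(k*n/n_classes)-th order
    statistic of the n input values — deterministic and independent of input
    order.
    """
    vals = sorted(float(v) for v in values)
    n = len(vals)
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if len(set(vals)) < n_classes:
        raise ValueError(
            f"need at least {n_classes} distinct values for {n_classes} classes"
        )
    breaks = tuple(
        vals[math.ceil(k * n / n_classes) - 1] for k in range(1, n_classes)
    )
    if len(set(breaks)) != len(breaks):
        raise ValueError("tied order statistics: quantile classes are degenerate")
    return breaks


# ---------------------------------------------------------------------------
# grid records
# ---------------------------------------------------------------------------

@dataclass
class GridRecord:
    """One grid cell's raw (pre-discretization) measurements."""

    cell_id: str | int
    landscape_type: str
    lulc_class: int
    slope: float  # degrees
    field_capacity: float  # mm, effective root zone
    nutrient_availability: float  # kmol_c/ha
    soil_texture: str
    wind_erosion: str
    water_erosion: str
    nitrate_leaching: str
    nitrogen_surplus: float  # kg N/ha; negative = net removal
    x: float | None = None
    y: float | None = None

    def __post_init__(self) -> None:
        for attr in ("slope", "field_capacity", "nutrient_availability"):
            if getattr(self, attr) < 0:
                raise ValueError(
                    f"cell {self.cell_id!r}: {attr} must be nonnegative, "
                    f"got {getattr(self, attr)!r}"
                )
        for node, value in (
            ("landscape_type", self.landscape_type),
            ("soil_texture", self.soil_texture),
            ("wind_erosion", self.wind_erosion),
            ("water_erosion", self.water_erosion),
            ("nitrate_leaching_potential", self.nitrate_leaching),
        ):
            if value not in NODE_STATES[node]:
                raise ValueError(
                    f"cell {self.cell_id!r}: {node} value {value!r} not in "
                    f"{list(NODE_STATES[node])}"
                )


#: a discretized cell: node name -> state label for the observed nodes
StateRecord = dict[str, str]


class ESMatrixTable:
    """Ecosystem-service matrix lookup: LULC class code -> potential score 0-5.

    Ships empty; per-class scores are supplied via configuration (toy tables
    in tests, a synthetic table in the generator defaults).
    """

    def __init__(self, scores: Mapping[int, int] | None = None) -> None:
        self.scores: dict[int, int] = {}
        for code, score in (scores or {}).items():
            code, score = int(code), int(score)
            if not 0 <= score <= 5:
                raise ValueError(f"ES score for LULC {code} must be in 0..5, got {score}")
            self.scores[code] = score

    def __contains__(self, code: int) -> bool:
        return int(code) in self.scores

    def score(self, code: int) -> int:
        try:
            return self.scores[int(code)]
        except KeyError:
            raise KeyError(
                f"LULC class {code!r} has no entry in the ES matrix table"
            ) from None


def lookup_preliminary_potential(lulc: int, matrix: ESMatrixTable) -> str:
    """Map a LULC class through the ES matrix to a potential state P_no..P_5."""
    s = matrix.score(lulc)
    return "P_no" if s == 0 else f"P_{s}"


DEFAULT_RECLASSIFICATION: dict[str, str] = {
    "P_no": "low",
    "P_1": "low",
    "P_2": "medium",
    "P_3": "medium",
    "P_4": "high",
    "P_5": "high",
}


def reclassify_potential(
    p: str, mapping: Mapping[str, str] | None = None
) -> str:
    """Collapse the 0-5 potential scale to low/medium/high."""
    mapping = dict(mapping) if mapping is not None else DEFAULT_RECLASSIFICATION
    try:
        return mapping[p]
    except KeyError:
        raise ValueError(f"unknown potential state {p!r}") from None


def budget_state(
    potential: str, demand: str, sustainable_on_tie: bool = True
) -> str:
    """Supply-demand balance: sustainable iff the reclassified potential
    outranks the demand (equal ranks count as sustainable by default)."""
    try:
        dp, dd = _LMH_RANK[potential], _LMH_RANK[demand]
    except KeyError as exc:
        raise ValueError(f"unknown potential/demand state {exc.args[0]!r}") from None
    if dp > dd or (dp == dd and sustainable_on_tie):
        return "sustainable"
    return "unsustainable"


def discretize_record(
    rec: GridRecord,
    scheme: DiscretizationScheme | None = None,
    matrix: ESMatrixTable | None = None,
) -> StateRecord:
    """Map one raw grid cell to a state assignment of the observed nodes."""
    scheme = scheme or default_scheme()
    if matrix is None:
        raise ValueError("an ES matrix table is required to discretize records")
    return {
        "landscape_type": rec.landscape_type,
        "soil_texture": rec.soil_texture,
        "slope": scheme.classify("slope", rec.slope),
        "field_capacity": scheme.classify("field_capacity", rec.field_capacity),
        "wind_erosion": rec.wind_erosion,
        "water_erosion": rec.water_erosion,
        "natural_nutrient_availability": scheme.classify(
            "natural_nutrient_availability", rec.nutrient_availability
        ),
        "nitrate_leaching_potential": rec.nitrate_leaching,
        "preliminary_potential": lookup_preliminary_potential(rec.lulc_class, matrix),
        "demand": scheme.classify("nitrogen_surplus", rec.nitrogen_surplus),
    }


# ---------------------------------------------------------------------------
# expert CPTs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpertCPTParams:
    """Parameters of the generated expert-style CPTs.

    erosion_peak/erosion_neighbor: probability mass on the class implied by
    the ordinal maximum of wind and water erosion, and on each adjacent
    class (clipped at the scale ends and renormalized).

    potential_peak/potential_neighbor: the same for the nutrient-regulation
    potential, whose peak is the preliminary potential shifted by -1/0/+1
    steps.  The shift follows a favourability score — ordinal ranks of field
    capacity and natural nutrient availability minus those of nitrate
    leaching and erosion (range -4..+4): at or below ``shift_down_max`` the
    site degrades the matrix potential one step, at or above
    ``shift_up_min`` it upgrades it one step, otherwise the matrix value
    stands.  The peak mass is deliberately < 1 so the conditional stays a
    distribution peaked at (a shift of) the preliminary state rather than a
    point mass.
    """

    erosion_peak: float = 0.7
    erosion_neighbor: float = 0.15
    potential_peak: float = 0.5
    potential_neighbor: float = 0.25
    shift_down_max: int = -2
    shift_up_min: int = 2
    reclassification: tuple[tuple[str, str], ...] = tuple(
        DEFAULT_RECLASSIFICATION.items()
    )
    sustainable_on_tie: bool = True

    def reclass_map(self) -> dict[str, str]:
        return dict(self.reclassification)


def _peaked_column(n_states: int, peak: int, peak_mass: float, nbr_mass: float) -> np.ndarray:
    col = np.zeros(n_states)
    col[peak] = peak_mass
    if peak - 1 >= 0:
        col[peak - 1] += nbr_mass
    if peak + 1 < n_states:
        col[peak + 1] += nbr_mass
    return col / col.sum()


def favourability_score(
    field_capacity: str,
    nutrient_availability: str,
    nitrate_leaching: str,
    erosion: str,
) -> int:
    """Site score in -4..+4: retention-friendly conditions (high field
    capacity and nutrient availability) count up, loss pathways (leaching,
    erosion) count down."""
    return (
        _LMH_RANK[field_capacity]
        + _LMH_RANK[nutrient_availability]
        - _LMH_RANK[nitrate_leaching]
        - _LMH_RANK[erosion]
    )


def default_expert_cpt(node: str, params: ExpertCPTParams | None = None) -> CPT:
    """Generate the CPT of one of the four expert nodes.

    See :class:`ExpertCPTParams` for the heuristics.  The reclassification
    and budget CPTs are deterministic (point-mass columns) images of
    :func:`reclassify_potential` and :func:`budget_state`.
    """
    params = params or ExpertCPTParams()
    if node == "erosion":
        wind, water = NODE_STATES["wind_erosion"], NODE_STATES["water_erosion"]
        # ordinal max of the two 4-level inputs, folded to low/medium/high
        fold = {0: 0, 1: 0, 2: 1, 3: 2}  # no,low -> low; medium -> medium; high -> high
        table = {}
        for wi, wa in itertools.product(wind, water):
            peak = fold[max(wind.index(wi), water.index(wa))]
            table[(wi, wa)] = _peaked_column(
                3, peak, params.erosion_peak, params.erosion_neighbor
            )
        return CPT("erosion", ("wind_erosion", "water_erosion"), table)
    if node == "nutrient_regulation_potential":
        lmh = ("low", "medium", "high")
        table = {}
        for fc, nna, nl, er, prelim in itertools.product(
            lmh, lmh, lmh, lmh, POTENTIAL_STATES
        ):
            score = favourability_score(fc, nna, nl, er)
            shift = (
                -1
                if score <= params.shift_down_max
                else 1 if score >= params.shift_up_min else 0
            )
            peak = min(max(POTENTIAL_STATES.index(prelim) + shift, 0), 5)
            table[(fc, nna, nl, er, prelim)] = _peaked_column(
                6, peak, params.potential_peak, params.potential_neighbor
            )
        return CPT(
            "nutrient_regulation_potential",
            (
                "field_capacity",
                "natural_nutrient_availability",
                "nitrate_leaching_potential",
                "erosion",
                "preliminary_potential",
            ),
            table,
        )
    if node == "reclassified_potential":
        mapping = params.reclass_map()
        table = {}
        for p in POTENTIAL_STATES:
            col = np.zeros(3)
            col[_LMH_RANK[reclassify_potential(p, mapping)]] = 1.0
            table[(p,)] = col
        return CPT("reclassified_potential", ("nutrient_regulation_potential",), table)
    if node == "budget":
        table = {}
        for pot, dem in itertools.product(("low", "medium", "high"), repeat=2):
            col = np.zeros(2)
            col[0 if budget_state(pot, dem, params.sustainable_on_tie) == "sustainable" else 1] = 1.0
            table[(pot, dem)] = col
        return CPT("budget", ("reclassified_potential", "demand"), table)
    raise ValueError(
        f"{node!r} is not an expert node; expected one of {list(EXPERT_NODES)}"
    )


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

def _node_specs() -> list[NodeSpec]:
    specs = []
    for name, states in NODE_STATES.items():
        rank = None
        if states == ("low", "medium", "high"):
            rank = (0, 1, 2)
        elif states == POTENTIAL_STATES:
            rank = tuple(range(6))
        specs.append(NodeSpec(name, states, rank))
    return specs


def build_network(
    expert_params: ExpertCPTParams | None = None,
    learned_cpts: Mapping[str, CPT] | None = None,
    arcs: Sequence[tuple[str, str]] | None = None,
) -> Network:
    """Assemble the 14-node model.

    Expert nodes get their generated CPTs; observed nodes take CPTs from
    ``learned_cpts`` when provided and uniform placeholder CPTs otherwise
    (so the structure is usable before parameter learning).
    """
    arcs = tuple(arcs) if arcs is not None else DEFAULT_ARCS
    net = Network(_node_specs(), arcs)
    for node in EXPERT_NODES:
        cpt = default_expert_cpt(node, expert_params)
        if net.parents(node) == cpt.parents:  # custom arc sets fall through to placeholders
            net.set_cpt(cpt)
    for node in net.nodes:
        if node in net.cpts:
            continue
        if learned_cpts and node in learned_cpts:
            net.set_cpt(learned_cpts[node])
            continue
        parents = net.parents(node)
        card = len(net.states(node))
        combos = itertools.product(*[net.states(p) for p in parents])
        table = {c: np.full(card, 1.0 / card) for c in combos}
        net.set_cpt(CPT(node, parents, table))
    return net
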