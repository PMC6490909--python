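"""Seeded synthetic landscape-grid generator.

Emulates the statistical structure of a Northern-German landscape grid:
three landscape types (Hügelland, Geest, Marsch) condition soil texture,
slope, land cover and nitrogen surplus; soil texture conditions field
capacity, natural nutrient availability, nitrate leaching and wind
erosion; slope conditions water erosion.  Cells are exchangeable rows
sampled ancestrally through the generating conditional tables; continuous
values are drawn uniformly within their class's emission range, which is
nested inside the corresponding discretization interval so that
discretizing a generated record returns exactly the sampled classes.

The default tables are fixtures: they encode the qualitative regional
contrasts (Geest sandy/leaching-prone/wind-exposed with higher demand,
Marsch flat, Hügelland hilly with silt/clay soils) at plausible
magnitudes.  They are not calibrated against any published CPT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import (
    NODE_STATES,
    ESMatrixTable,
    GridRecord,
    lookup_preliminary_potential,
)

__all__ = ["GeneratorConfig", "default_generator_config", "generate_grid"]

_ATOL = 1e-9


def _check_dist(name: str, dist: Mapping[str, float], states: Sequence) -> None:
    if set(dist) != set(states):
        raise ValueError(
            f"{name}: categories {sorted(dist)} != expected {sorted(str(s) for s in states)}"
        )
    total = sum(dist.values())
    if abs(total - 1.0) > _ATOL:
        raise ValueError(f"{name}: probabilities sum to {total!r}, not 1")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{name}: negative probability")


@dataclass
class GeneratorConfig:
    """Generating distributions and emission ranges for the synthetic grid.

    Conditional tables map a parent state to a distribution over child
    categories.  ``emission`` maps each continuous variable's class to the
    (lo, hi) range its values are drawn from, uniformly.
    """

    n_cells: int
    seed: int
    landscape_props: dict[str, float]
    texture_given_landscape: dict[str, dict[str, float]]
    slope_class_given_landscape: dict[str, dict[str, float]]
    lulc_given_landscape: dict[str, dict[int, float]]
    surplus_class_given_landscape: dict[str, dict[str, float]]
    field_capacity_class_given_texture: dict[str, dict[str, float]]
    nutrient_class_given_texture: dict[str, dict[str, float]]
    leaching_given_texture: dict[str, dict[str, float]]
    wind_erosion_given_texture: dict[str, dict[str, float]]
    water_erosion_given_slope_class: dict[str, dict[str, float]]
    emission: dict[str, dict[str, tuple[float, float]]]
    es_scores: dict[int, int]
    grid_cols: int = 0  # 0: derive a near-square grid
    grid_spacing: float = 200.0  # metres

    def es_matrix(self) -> ESMatrixTable:
        return ESMatrixTable(self.es_scores)

    def validate(self) -> None:
        _check_dist("landscape_props", self.landscape_props, NODE_STATES["landscape_type"])
        conditionals: list[tuple[str, dict, Sequence]] = [
            ("texture|landscape", self.texture_given_landscape, NODE_STATES["soil_texture"]),
            ("slope|landscape", self.slope_class_given_landscape, ("low", "medium", "high")),
            ("lulc|landscape", self.lulc_given_landscape, sorted(self.es_scores)),
            ("surplus|landscape", self.surplus_class_given_landscape, ("low", "medium", "high")),
            ("field_capacity|texture", self.field_capacity_class_given_texture, ("low", "medium", "high")),
            ("nutrients|texture", self.nutrient_class_given_texture, ("low", "medium", "high")),
            ("leaching|texture", self.leaching_given_texture, ("low", "medium", "high")),
            ("wind|texture", self.wind_erosion_given_texture, NODE_STATES["wind_erosion"]),
            ("water|slope", self.water_erosion_given_slope_class, NODE_STATES["water_erosion"]),
        ]
        for name, table, states in conditionals:
            for parent, dist in table.items():
                _check_dist(f"{name}[{parent}]", dist, states)
        for var, ranges in self.emission.items():
            for cls, (lo, hi) in ranges.items():
                if not lo <= hi:
                    raise ValueError(f"emission range {var}[{cls}] is empty: ({lo}, {hi})")

    # generating distributions the model should recover after learning ----
    def implied_cpts(self) -> dict[str, dict[tuple[str, ...], dict[str, float]]]:
        """The conditional tables expressed on the model's nodes.

        The preliminary-potential table is the LULC table pushed through the
        ES matrix (several land-cover classes may share a potential state).
        """
        out: dict[str, dict[tuple[str, ...], dict[str, float]]] = {
            "landscape_type": {(): dict(self.landscape_props)},
            "soil_texture": {(l,): dict(d) for l, d in self.texture_given_landscape.items()},
            "slope": {(l,): dict(d) for l, d in self.slope_class_given_landscape.items()},
            "demand": {(l,): dict(d) for l, d in self.surplus_class_given_landscape.items()},
            "field_capacity": {(t,): dict(d) for t, d in self.field_capacity_class_given_texture.items()},
            "natural_nutrient_availability": {(t,): dict(d) for t, d in self.nutrient_class_given_texture.items()},
            "nitrate_leaching_potential": {(t,): dict(d) for t, d in self.leaching_given_texture.items()},
            "wind_erosion": {(t,): dict(d) for t, d in self.wind_erosion_given_texture.items()},
            "water_erosion": {(s,): dict(d) for s, d in self.water_erosion_given_slope_class.items()},
        }
        matrix = self.es_matrix()
        prelim: dict[tuple[str, ...], dict[str, float]] = {}
        for l, dist in self.lulc_given_landscape.items():
            acc = {s: 0.0 for s in NODE_STATES["preliminary_potential"]}
            for code, p in dist.items():
                acc[lookup_preliminary_potential(code, matrix)] += p
            prelim[(l,)] = acc
        out["preliminary_potential"] = prelim
        return out

    def parent_state_probability(self, node: str, combo: tuple[str, ...]) -> float:
        """Marginal probability of a learned node's parent combination under
        the generating process (for expected-count bookkeeping)."""
        if not combo:
            return 1.0
        (pstate,) = combo
        parent_of = {
            "soil_texture": "landscape_type",
            "slope": "landscape_type",
            "demand": "landscape_type",
            "preliminary_potential": "landscape_type",
            "field_capacity": "soil_texture",
            "natural_nutrient_availability": "soil_texture",
            "nitrate_leaching_potential": "soil_texture",
            "wind_erosion": "soil_texture",
            "water_erosion": "slope",
        }
        parent = parent_of[node]
        if parent == "landscape_type":
            return self.landscape_props[pstate]
        if parent == "soil_texture":
            return sum(
                self.landscape_props[l] * self.texture_given_landscape[l][pstate]
                for l in self.landscape_props
            )
        return sum(  # slope classes
            self.landscape_props[l] * self.slope_class_given_landscape[l][pstate]
            for l in self.landscape_props
        )


def _draw(rng: np.random.Generator, dist: Mapping, n: int) -> np.ndarray:
    cats = list(dist)
    probs = np.array([dist[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(cats), size=n, p=probs)
    return np.array(cats, dtype=object)[idx]


def _conditional_draw(
    rng: np.random.Generator, parents: np.ndarray, table: Mapping[str, Mapping], n: int
) -> np.ndarray:
    out = np.empty(n, dtype=object)
    for parent, dist in table.items():
        mask = parents == parent
        m = int(mask.sum())
        if m:
            out[mask] = _draw(rng, dist, m)
    return out


def _emit(
    rng: np.random.Generator,
    classes: np.ndarray,
    ranges: Mapping[str, tuple[float, float]],
) -> np.ndarray:
    vals = np.empty(len(classes), dtype=float)
    for cls, (lo, hi) in ranges.items():
        mask = classes == cls
        m = int(mask.sum())
        if m:
            vals[mask] = rng.uniform(lo, hi, size=m)
    return vals


def generate_grid(cfg: GeneratorConfig) -> list[GridRecord]:
    """Sample ``cfg.n_cells`` grid records; deterministic for a given seed."""
    cfg.validate()
    n = cfg.n_cells
    rng = np.random.default_rng(cfg.seed)
    landscape = _draw(rng, cfg.landscape_props, n)
    texture = _conditional_draw(rng, landscape, cfg.texture_given_landscape, n)
    slope_cls = _conditional_draw(rng, landscape, cfg.slope_class_given_landscape, n)
    lulc = _conditional_draw(rng, landscape, cfg.lulc_given_landscape, n)
    surplus_cls = _conditional_draw(rng, landscape, cfg.surplus_class_given_landscape, n)
    fc_cls = _conditional_draw(rng, texture, cfg.field_capacity_class_given_texture, n)
    nna_cls = _conditional_draw(rng, texture, cfg.nutrient_class_given_texture, n)
    leaching = _conditional_draw(rng, texture, cfg.leaching_given_texture, n)
    wind = _conditional_draw(rng, texture, cfg.wind_erosion_given_texture, n)
    water = _conditional_draw(rng, slope_cls, cfg.water_erosion_given_slope_class, n)
    slope_vals = _emit(rng, slope_cls, cfg.emission["slope"])
    fc_vals = _emit(rng, fc_cls, cfg.emission["field_capacity"])
    nna_vals = _emit(rng, nna_cls, cfg.emission["nutrient_availability"])
    surplus_vals = _emit(rng, surplus_cls, cfg.emission["nitrogen_surplus"])
    cols = cfg.grid_cols or int(np.ceil(np.sqrt(n)))
    records = []
    for i in range(n):
        records.append(
            GridRecord(
                cell_id=i,
                landscape_type=str(landscape[i]),
                lulc_class=int(lulc[i]),
                slope=float(slope_vals[i]),
                field_capacity=float(fc_vals[i]),
                nutrient_availability=float(nna_vals[i]),
                soil_texture=str(texture[i]),
                wind_erosion=str(wind[i]),
                water_erosion=str(water[i]),
                nitrate_leaching=str(leaching[i]),
                nitrogen_surplus=float(surplus_vals[i]),
                x=(i % cols) * cfg.grid_spacing,
                y=(i // cols) * cfg.grid_spacing,
            )
        )
    return records


def default_generator_config(
    region: str = "schleswig-holstein", n_cells: int = 5000, seed: int = 0
) -> GeneratorConfig:
    """Generator defaults for the two study regions.

    'schleswig-holstein' mixes all three landscape types; 'bornhoeved'
    contains only Hügelland and Geest (no Marsch) and shifts the nitrogen
    surplus upward so demand peaks at medium rather than low.
    """
    if region == "schleswig-holstein":
        landscape_props = {"huegelland": 0.40, "geest": 0.43, "marsch": 0.17}
        surplus = {
            "huegelland": {"low": 0.55, "medium": 0.30, "high": 0.15},
            "geest": {"low": 0.35, "medium": 0.35, "high": 0.30},
            "marsch": {"low": 0.50, "medium": 0.30, "high": 0.20},
        }
    elif region == "bornhoeved":
        landscape_props = {"huegelland": 0.60, "geest": 0.40, "marsch": 0.0}
        surplus = {
            "huegelland": {"low": 0.30, "medium": 0.45, "high": 0.25},
            "geest": {"low": 0.20, "medium": 0.40, "high": 0.40},
            "marsch": {"low": 0.50, "medium": 0.30, "high": 0.20},
        }
    else:
        raise ValueError(
            f"unknown region {region!r}; expected 'schleswig-holstein' or 'bornhoeved'"
        )
    # synthetic ES-matrix scores for the generator's CORINE-style land covers:
    # 112 urban, 211 arable, 231 pasture, 311/312 forest, 412 peat bog
    es_scores = {112: 0, 211: 1, 231: 2, 311: 5, 312: 4, 412: 3}
    return GeneratorConfig(
        n_cells=n_cells,
        seed=seed,
        landscape_props=landscape_props,
        texture_given_landscape={
            "huegelland": {"sand": 0.20, "peat": 0.05, "silt_clay": 0.65, "other": 0.10},
            "geest": {"sand": 0.70, "peat": 0.15, "silt_clay": 0.10, "other": 0.05},
            "marsch": {"sand": 0.10, "peat": 0.10, "silt_clay": 0.75, "other": 0.05},
        },
        slope_class_given_landscape={
            "huegelland": {"low": 0.15, "medium": 0.35, "high": 0.50},
            "geest": {"low": 0.40, "medium": 0.40, "high": 0.20},
            "marsch": {"low": 0.80, "medium": 0.15, "high": 0.05},
        },
        lulc_given_landscape={
            "huegelland": {211: 0.50, 231: 0.20, 311: 0.15, 312: 0.03, 412: 0.02, 112: 0.10},
            "geest": {211: 0.35, 231: 0.25, 311: 0.05, 312: 0.20, 412: 0.08, 112: 0.07},
            "marsch": {211: 0.35, 231: 0.50, 311: 0.03, 312: 0.01, 412: 0.01, 112: 0.10},
        },
        surplus_class_given_landscape=surplus,
        field_capacity_class_given_texture={
            "sand": {"low": 0.70, "medium": 0.25, "high": 0.05},
            "peat": {"low": 0.10, "medium": 0.30, "high": 0.60},
            "silt_clay": {"low": 0.10, "medium": 0.45, "high": 0.45},
            "other": {"low": 0.33, "medium": 0.34, "high": 0.33},
        },
        nutrient_class_given_texture={
            "sand": {"low": 0.70, "medium": 0.25, "high": 0.05},
            "peat": {"low": 0.30, "medium": 0.40, "high": 0.30},
            "silt_clay": {"low": 0.10, "medium": 0.40, "high": 0.50},
            "other": {"low": 0.33, "medium": 0.34, "high": 0.33},
        },
        leaching_given_texture={
            "sand": {"low": 0.10, "medium": 0.25, "high": 0.65},
            "peat": {"low": 0.40, "medium": 0.40, "high": 0.20},
            "silt_clay": {"low": 0.60, "medium": 0.30, "high": 0.10},
            "other": {"low": 0.34, "medium": 0.33, "high": 0.33},
        },
        wind_erosion_given_texture={
            "sand": {"no": 0.15, "low": 0.25, "medium": 0.30, "high": 0.30},
            "peat": {"no": 0.30, "low": 0.30, "medium": 0.25, "high": 0.15},
            "silt_clay": {"no": 0.50, "low": 0.30, "medium": 0.15, "high": 0.05},
            "other": {"no": 0.40, "low": 0.30, "medium": 0.20, "high": 0.10},
        },
        water_erosion_given_slope_class={
            "low": {"no": 0.70, "low": 0.20, "medium": 0.08, "high": 0.02},
            "medium": {"no": 0.30, "low": 0.35, "medium": 0.25, "high": 0.10},
            "high": {"no": 0.10, "low": 0.25, "medium": 0.35, "high": 0.30},
        },
        # emission ranges sit strictly inside the discretization intervals
        emission={
            "slope": {"low": (0.0, 0.2039), "medium": (0.21, 0.6581), "high": (0.66, 13.44)},
            "field_capacity": {"low": (50.0, 199.0), "medium": (200.0, 300.0), "high": (301.0, 450.0)},
            "nutrient_availability": {"low": (50.0, 299.0), "medium": (300.0, 600.0), "high": (601.0, 900.0)},
            "nitrogen_surplus": {"low": (-20.0, 40.0), "medium": (41.0, 60.0), "high": (61.0, 140.0)},
        },
        es_scores=es_scores,
    )
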