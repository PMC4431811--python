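"""Synthetic two-photon-like track experiments with known ground truth.

The generator reproduces the *structure* of an in-vivo motility experiment:
imaging dates, mice nested in dates, lymph nodes in mice, microscopic fields
in nodes, and cells tracked within fields.  Each hierarchy level contributes
an additive random effect on log mean speed, so the data carry exactly the
dependence structure the nested analyses are designed to absorb.

Motion is a persistent random walk in a 3D imaging box: each cell has a mean
speed (log-normal across cells) and a persistence parameter kappa; step
directions concentrate around the previous heading von-Mises-Fisher style
(kappa = 0 gives uniform directions, i.e. a mean turning angle of 90 deg).
Per-step speeds are multiplicatively log-normal.  With boundary censoring on,
a track ends when the cell leaves the box, which over-represents slow cells
in step-pooled data -- the sampling bias the mixed models correct.

Population, dye and interaction effects enter in sum-to-zero form on
log-speed (and optionally on log-kappa), so a factorial ANOVA of log speed
estimates exactly the configured coefficients.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .io import TrackSet, trackset_from_frame

__all__ = [
    "Design",
    "SimConfig",
    "GroundTruth",
    "simulate_experiment",
    "paper_like_config",
]

_LEVEL_SIGMAS = ("sigma_date", "sigma_mouse", "sigma_node", "sigma_field", "sigma_cell")


@dataclass(frozen=True)
class Design:
    """Totals per hierarchy level.

    Children are assigned to parents round-robin, so totals that are not
    multiples of each other (e.g. 6 mice over 5 dates) are honoured exactly.
    """

    n_dates: int = 2
    n_mice: int = 4
    n_nodes: int = 6
    n_fields: int = 8
    cells_per_field: int = 10
    max_frames: int = 30

    def __post_init__(self):
        for name in ("n_dates", "n_mice", "n_nodes", "n_fields",
                     "cells_per_field", "max_frames"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (self.n_dates <= self.n_mice <= self.n_nodes <= self.n_fields):
            raise ValueError("level totals must be nondecreasing down the hierarchy")


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of a synthetic experiment.

    Fixed effects are sum-to-zero coefficients on log speed (um/min): the
    first population/dye level gets +effect, the second -effect.  Sigmas are
    standard deviations of the additive random effects on log speed;
    ``sigma_step`` is the per-step multiplicative log-normal noise.
    ``kappa`` is the persistence concentration (0 = uniform turning).
    """

    design: Design = field(default_factory=Design)
    dt: float = 20.0                      # seconds per frame
    baseline_log_speed: float = float(np.log(8.0))
    population_effect: float = 0.0
    dye_effect: float = 0.0
    interaction_effect: float = 0.0
    population_effect_log_kappa: float = 0.0
    dye_effect_log_kappa: float = 0.0
    interaction_effect_log_kappa: float = 0.0
    sigma_date: float = 0.0
    sigma_mouse: float = 0.0
    sigma_node: float = 0.0
    sigma_field: float = 0.0
    sigma_cell: float = 0.3
    sigma_step: float = 0.3
    kappa: float = 1.0
    volume: tuple = (300.0, 300.0, 50.0)  # um
    censor_on_exit: bool = True
    populations: tuple = ("WT", "KO")
    dyes: tuple = ("CFSE", "CMTMR")
    dye_weights: dict | None = None       # population -> P(first dye); None = balanced
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in _LEVEL_SIGMAS + ("sigma_step",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"] = asdict(self.design)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "design" in d:
            d["design"] = Design(**d["design"])
        if "volume" in d:
            d["volume"] = tuple(d["volume"])
        for k in ("populations", "dyes"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruth:
    """Realised random effects and per-cell true parameters."""

    config: SimConfig
    level_effects: dict                  # level -> {unit label: effect}
    cells: pd.DataFrame                  # per-cell truth table

    def to_json(self) -> str:
        payload = {
            "config": self.config.to_dict(),
            "level_effects": self.level_effects,
            "cells": self.cells.to_dict(orient="list"),
        }
        return json.dumps(payload, indent=2)


def _round_robin(n_children: int, n_parents: int) -> np.ndarray:
    return np.arange(n_children) % n_parents


def _unit_sphere(rng, n) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _vmf_step(rng, prev: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    """Directions concentrated around ``prev`` with per-row concentration."""
    n = len(prev)
    u = rng.random(n)
    w = np.empty(n)
    small = kappa < 1e-8
    w[small] = 1.0 - 2.0 * u[small]
    k = kappa[~small]
    if k.size:
        # inverse-CDF sampling of cos(angle) under vMF (Ulrich/Wood)
        expm2k = np.exp(-2.0 * k)
        w[~small] = 1.0 + np.log(u[~small] + (1.0 - u[~small]) * expm2k) / k
    w = np.clip(w, -1.0, 1.0)
    # orthonormal frame around prev
    helper = np.zeros_like(prev)
    helper[:, 0] = 1.0
    swap = np.abs(prev[:, 0]) > 0.9
    helper[swap] = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(prev, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(prev, e1)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sint = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
    return (w[:, None] * prev
            + sint[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2))


def simulate_experiment(cfg: SimConfig) -> tuple[TrackSet, GroundTruth]:
    """Generate one synthetic experiment.

    Returns the tracks (canonical schema, hierarchy IDs included) and the
    ground truth.  The same config (same seed) regenerates both bit-for-bit.
    """
    rng = np.random.default_rng(cfg.seed)
    dz = cfg.design

    # hierarchy allocation (round robin), labels unique only within parent
    mouse_parent = _round_robin(dz.n_mice, dz.n_dates)
    node_parent = _round_robin(dz.n_nodes, dz.n_mice)
    field_parent = _round_robin(dz.n_fields, dz.n_nodes)
    n_cells = dz.n_fields * dz.cells_per_field
    cell_field = np.repeat(np.arange(dz.n_fields), dz.cells_per_field)

    date_lab = np.array([f"day{i + 1}" for i in range(dz.n_dates)])
    within = {}
    for name, parent, n in (("mouse", mouse_parent, dz.n_mice),
                            ("node", node_parent, dz.n_nodes),
                            ("field", field_parent, dz.n_fields)):
        idx = np.zeros(n, int)
        seen: dict = {}
        for i, p in enumerate(parent):
            idx[i] = seen.get(p, 0)
            seen[p] = idx[i] + 1
        within[name] = idx
    mouse_lab = np.array([f"mouse{k + 1}" for k in within["mouse"]])
    node_lab = np.array([f"LN{k + 1}" for k in within["node"]])
    field_lab = np.array([f"field{k + 1}" for k in within["field"]])

    b_date = rng.normal(0.0, cfg.sigma_date, dz.n_dates)
    b_mouse = rng.normal(0.0, cfg.sigma_mouse, dz.n_mice)
    b_node = rng.normal(0.0, cfg.sigma_node, dz.n_nodes)
    b_field = rng.normal(0.0, cfg.sigma_field, dz.n_fields)
    b_cell = rng.normal(0.0, cfg.sigma_cell, n_cells)

    # treatment assignment: populations alternate within field (balanced);
    # dyes are drawn with per-population weights (0.5 = balanced)
    population = np.array(
        [cfg.populations[i % 2] for i in range(dz.cells_per_field)] * dz.n_fields
    )
    p_first_dye = np.array([
        0.5 if cfg.dye_weights is None else float(cfg.dye_weights[p])
        for p in population
    ])
    dye = np.where(rng.random(n_cells) < p_first_dye, cfg.dyes[0], cfg.dyes[1])

    s_pop = np.where(population == cfg.populations[0], 1.0, -1.0)
    s_dye = np.where(dye == cfg.dyes[0], 1.0, -1.0)
    cell_node = field_parent[cell_field]
    cell_mouse = node_parent[cell_node]
    cell_date = mouse_parent[cell_mouse]

    mu_cell = (cfg.baseline_log_speed
               + cfg.population_effect * s_pop
               + cfg.dye_effect * s_dye
               + cfg.interaction_effect * s_pop * s_dye
               + b_date[cell_date] + b_mouse[cell_mouse]
               + b_node[cell_node] + b_field[cell_field] + b_cell)
    speed_cell = np.exp(mu_cell)          # um/min
    log_kappa_off = (cfg.population_effect_log_kappa * s_pop
                     + cfg.dye_effect_log_kappa * s_dye
                     + cfg.interaction_effect_log_kappa * s_pop * s_dye)
    kappa_cell = cfg.kappa * np.exp(log_kappa_off)

    # motion: all cells advance frame-by-frame in lockstep
    vol = np.asarray(cfg.volume, float)
    if np.any(np.exp(cfg.baseline_log_speed) * cfg.dt / 60.0 > vol):
        import warnings
        warnings.warn("imaging volume is smaller than a typical step",
                      stacklevel=2)
    pos = rng.uniform(0.0, 1.0, (n_cells, 3)) * vol
    heading = _unit_sphere(rng, n_cells)
    alive = np.ones(n_cells, bool)
    traj = [pos.copy()]
    alive_hist = [alive.copy()]
    for _ in range(dz.max_frames):
        heading = np.where(
            alive[:, None], _vmf_step(rng, heading, kappa_cell), heading
        )
        step_len = (speed_cell
                    * np.exp(cfg.sigma_step * rng.standard_normal(n_cells))
                    * cfg.dt / 60.0)
        new_pos = pos + heading * step_len[:, None]
        inside = np.all((new_pos >= 0.0) & (new_pos <= vol), axis=1)
        if cfg.censor_on_exit:
            stepped = alive & inside
            alive = stepped
        else:
            stepped = alive.copy()  # cells may wander outside the box
        pos = np.where(stepped[:, None], new_pos, pos)
        traj.append(pos.copy())
        alive_hist.append(stepped.copy())
        if not alive.any():
            break

    # assemble long table: cell c contributes frames 0..n_frames(c)
    alive_mat = np.vstack(alive_hist)          # (frames+1, n_cells)
    traj_mat = np.stack(traj)                  # (frames+1, n_cells, 3)
    n_frames = alive_mat.cumprod(axis=0).sum(axis=0).astype(int)  # points/cell
    track_lab = np.array(
        [f"track{(c % dz.cells_per_field) + 1}" for c in range(n_cells)]
    )
    cell_of_row = np.repeat(np.arange(n_cells), n_frames)
    frame_of_row = np.concatenate([np.arange(T) for T in n_frames])
    frame = pd.DataFrame({
        "date": date_lab[cell_date][cell_of_row],
        "mouse": mouse_lab[cell_mouse][cell_of_row],
        "lymph_node": node_lab[cell_node][cell_of_row],
        "field": field_lab[cell_field][cell_of_row],
        "track_id": track_lab[cell_of_row],
        "population": population[cell_of_row],
        "dye": dye[cell_of_row],
        "time_s": frame_of_row * cfg.dt,
        "x_um": traj_mat[frame_of_row, cell_of_row, 0],
        "y_um": traj_mat[frame_of_row, cell_of_row, 1],
        "z_um": traj_mat[frame_of_row, cell_of_row, 2],
    })
    ts = trackset_from_frame(frame, provenance=f"simulated(seed={cfg.seed})")

    level_effects = {
        "date": {date_lab[i]: float(b_date[i]) for i in range(dz.n_dates)},
        "mouse": {f"{date_lab[mouse_parent[i]]}|{mouse_lab[i]}": float(b_mouse[i])
                  for i in range(dz.n_mice)},
        "lymph_node": {f"node{i}": float(b_node[i]) for i in range(dz.n_nodes)},
        "field": {f"field{i}": float(b_field[i]) for i in range(dz.n_fields)},
    }
    cells = pd.DataFrame({
        "cell_index": np.arange(n_cells),
        "date": date_lab[cell_date],
        "mouse": mouse_lab[cell_mouse],
        "lymph_node": node_lab[cell_node],
        "field": field_lab[cell_field],
        "track_id": track_lab,
        "population": population,
        "dye": dye,
        "true_log_speed": mu_cell,
        "true_mean_speed": speed_cell,
        "true_kappa": kappa_cell,
        "cell_effect": b_cell,
        "n_points": n_frames.astype(int),
    })
    return ts, GroundTruth(config=cfg, level_effects=level_effects, cells=cells)


_PRESETS = {
    # hierarchy shapes of the four experimental datasets, desk-scaled in
    # cells per field; max_frames approximates the observed steps/track
    "pkc": dict(n_dates=5, n_mice=6, n_nodes=7, n_fields=9,
                cells_per_field=12, max_frames=30),
    "carma1": dict(n_dates=6, n_mice=10, n_nodes=17, n_fields=22,
                   cells_per_field=8, max_frames=33),
    "ccr7": dict(n_dates=2, n_mice=2, n_nodes=7, n_fields=8,
                 cells_per_field=10, max_frames=12),
    "ptx": dict(n_dates=7, n_mice=10, n_nodes=17, n_fields=22,
                cells_per_field=8, max_frames=27),
}

_PRESET_DYES = {
    "pkc": ("CFSE", "CMTMR"), "carma1": ("CFSE", "CMTMR"),
    "ptx": ("CFSE", "CMTMR"), "ccr7": ("CMFDA", "fura"),
}
_PRESET_POPS = {
    "pkc": ("WT", "KO"), "carma1": ("WT", "KO"),
    "ccr7": ("WT", "KO"), "ptx": ("suB", "PTX"),
}


def paper_like_config(dataset: str, seed: int = 0, **overrides) -> SimConfig:
    """Desk-scale SimConfig whose hierarchy mirrors one of the four datasets
    ("pkc", "carma1", "ccr7", "ptx")."""
    try:
        shape = _PRESETS[dataset]
    except KeyError:
        raise ValueError(
            f"unknown dataset {dataset!r}; choose from {sorted(_PRESETS)}"
        ) from None
    cfg = SimConfig(
        design=Design(**shape),
        populations=_PRESET_POPS[dataset],
        dyes=_PRESET_DYES[dataset],
        sigma_mouse=0.05, sigma_node=0.05, sigma_field=0.05,
        sigma_cell=0.35, sigma_step=0.35,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg
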