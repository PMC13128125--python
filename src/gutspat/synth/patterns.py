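"""Synthetic point-pattern generators with known ground truth.

Three classical processes span the clustered / random / regular spectrum:

* homogeneous (or inhomogeneous) Poisson — complete spatial randomness,
* Thomas cluster process — Poisson parents with Gaussian-dispersed
  offspring; its K function has the closed form
  K(r) = pi r^2 + (1/kappa) (1 - exp(-r^2 / (4 sigma^2))),
* Matérn type-II hard core — Poisson proposals thinned to a minimum
  pairwise distance.

A fourth generator emulates microcolony formation in a gel-like medium:
synchronous cell division with small placement jitter, punctuated by
shear events that scatter whole lineages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from ..geometry import PointPattern, Window

IntensityFn = Callable[[np.ndarray, np.ndarray], np.ndarray]


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_poisson_pattern(
    intensity: float | IntensityFn,
    window: Window,
    seed: int | np.random.Generator = 0,
) -> PointPattern:
    """Simulate a Poisson process with constant or functional intensity.

    A functional intensity lambda(x, y) (per µm²) is simulated by thinning
    a dominating homogeneous process at the intensity's maximum over a
    coarse evaluation grid.
    """
    rng = _rng(seed)
    if callable(intensity):
        gx, gy = np.meshgrid(
            np.linspace(window.xmin, window.xmax, 101),
            np.linspace(window.ymin, window.ymax, 101),
        )
        vals = np.asarray(intensity(gx, gy), float)
        if np.any(vals < 0):
            raise ValueError("intensity function must be nonnegative")
        lam_max = float(vals.max())
        if lam_max == 0:
            return PointPattern(window, np.empty((0, 2)))
        n = rng.poisson(lam_max * window.area)
        x = rng.uniform(window.xmin, window.xmax, n)
        y = rng.uniform(window.ymin, window.ymax, n)
        keep = rng.uniform(0, 1, n) < np.asarray(intensity(x, y), float) / lam_max
        return PointPattern(window, np.column_stack([x[keep], y[keep]]))
    lam = float(intensity)
    if lam < 0:
        raise ValueError("intensity must be nonnegative")
    n = rng.poisson(lam * window.area)
    x = rng.uniform(window.xmin, window.xmax, n)
    y = rng.uniform(window.ymin, window.ymax, n)
    return PointPattern(window, np.column_stack([x, y]))


def gen_thomas_pattern(
    parent_intensity: float,
    mean_offspring: float,
    offspring_sigma: float,
    window: Window,
    seed: int | np.random.Generator = 0,
) -> PointPattern:
    """Simulate a Thomas cluster process in ``window``.

    Parents are simulated in the window expanded by 4*sigma on every side
    so that clusters straddling the boundary contribute their share of
    offspring (standard guard-margin practice for cluster processes).
    """
    if parent_intensity <= 0:
        raise ValueError("parent_intensity must be positive")
    if mean_offspring < 0 or offspring_sigma < 0:
        raise ValueError("mean_offspring and offspring_sigma must be nonnegative")
    rng = _rng(seed)
    g = 4.0 * offspring_sigma
    big = Window(window.xmin - g, window.xmax + g, window.ymin - g, window.ymax + g)
    n_par = rng.poisson(parent_intensity * big.area)
    px = rng.uniform(big.xmin, big.xmax, n_par)
    py = rng.uniform(big.ymin, big.ymax, n_par)
    counts = rng.poisson(mean_offspring, n_par)
    cx = np.repeat(px, counts)
    cy = np.repeat(py, counts)
    total = int(counts.sum())
    off = rng.normal(0.0, offspring_sigma, (total, 2)) if total else np.empty((0, 2))
    x = cx + off[:, 0]
    y = cy + off[:, 1]
    keep = window.contains(x, y)
    return PointPattern(window, np.column_stack([x[keep], y[keep]]))


def thomas_K(r: np.ndarray, parent_intensity: float, offspring_sigma: float) -> np.ndarray:
    """Closed-form K function of the Thomas process (oracle for tests)."""
    r = np.asarray(r, float)
    if offspring_sigma == 0:
        extra = np.where(r > 0, 1.0 / parent_intensity, 0.0)
    else:
        extra = (1.0 / parent_intensity) * (
            1.0 - np.exp(-(r**2) / (4.0 * offspring_sigma**2))
        )
    return np.pi * r**2 + extra


def gen_hardcore_pattern(
    proposal_intensity: float,
    hardcore_radius: float,
    window: Window,
    seed: int | np.random.Generator = 0,
) -> PointPattern:
    """Simulate a Matérn type-II hard-core process.

    Poisson proposals receive i.i.d. uniform age marks; a proposal is
    deleted if any neighbour within ``hardcore_radius`` carries a smaller
    mark. The surviving pattern has minimum pairwise distance at least
    ``hardcore_radius``.
    """
    if hardcore_radius < 0:
        raise ValueError("hardcore_radius must be nonnegative")
    rng = _rng(seed)
    prop = gen_poisson_pattern(proposal_intensity, window, rng)
    if hardcore_radius == 0 or prop.n == 0:
        return prop
    ages = rng.uniform(0, 1, prop.n)
    tree = cKDTree(prop.points)
    pairs = tree.query_pairs(hardcore_radius, output_type="ndarray")
    keep = np.ones(prop.n, bool)
    for i, j in pairs:
        if ages[i] < ages[j]:
            keep[j] = False
        else:
            keep[i] = False
    return prop.subset(keep)


@dataclass(frozen=True)
class GrowthDispersalConfig:
    """Parameters of the growth-and-scatter microcolony simulator.

    Cells divide synchronously each generation, placing the daughter a
    small normal jitter away from the mother (growth in a gel that holds
    offspring in place). Every ``event_period`` generations a shear event
    occurs, and each lineage (founder clone) is independently scattered
    with probability ``dispersal_fraction``: its cells are re-placed
    uniformly in the window and become new singleton lineages. This is a
    minimal, non-canonical stand-in for growth punctuated by peristaltic
    mixing; every rule is a configuration knob.
    """

    n_founders: int
    generations: int
    division_jitter_sigma: float
    event_period: int = 0  # 0 disables shear events
    dispersal_fraction: float = 0.0
    seed: int = 0
    max_cells: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        if self.division_jitter_sigma < 0:
            raise ValueError("division_jitter_sigma must be >= 0")
        if not 0.0 <= self.dispersal_fraction <= 1.0:
            raise ValueError("dispersal_fraction must lie in [0, 1]")


def gen_growth_dispersal_pattern(
    config: GrowthDispersalConfig, window: Window
) -> PointPattern:
    """Run the growth-dispersal simulator; cells leaving the window are removed."""
    rng = np.random.default_rng(config.seed)
    x = rng.uniform(window.xmin, window.xmax, config.n_founders)
    y = rng.uniform(window.ymin, window.ymax, config.n_founders)
    lineage = np.arange(config.n_founders)
    next_lineage = config.n_founders

    for gen in range(1, config.generations + 1):
        if 2 * len(x) > config.max_cells:
            raise RuntimeError(
                f"population cap exceeded ({2 * len(x)} > {config.max_cells} cells)"
            )
        jit = rng.normal(0.0, config.division_jitter_sigma, (len(x), 2))
        x = np.concatenate([x, x + jit[:, 0]])
        y = np.concatenate([y, y + jit[:, 1]])
        lineage = np.concatenate([lineage, lineage])
        inside = window.contains(x, y)
        x, y, lineage = x[inside], y[inside], lineage[inside]

        if config.event_period and gen % config.event_period == 0:
            for lin in np.unique(lineage):
                if rng.uniform() < config.dispersal_fraction:
                    idx = np.flatnonzero(lineage == lin)
                    x[idx] = rng.uniform(window.xmin, window.xmax, len(idx))
                    y[idx] = rng.uniform(window.ymin, window.ymax, len(idx))
                    lineage[idx] = np.arange(next_lineage, next_lineage + len(idx))
                    next_lineage += len(idx)

    return PointPattern(window, np.column_stack([x, y]))
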