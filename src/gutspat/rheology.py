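"""Yield-stress estimation from oscillatory amplitude sweeps and creep tests.

Gut content behaves as a yield-stress material: solid-like below a
critical shear stress, fluid-like above it. Three complementary readouts
are implemented:

* **intersection** — stress vs. strain follows two power-law regimes; the
  yield point is the intersection of log-log line fits below and above
  yielding (stress coordinate = yield stress).
* **crossover** — the strain where the storage modulus G' falls below the
  loss modulus G'' marks the solid-to-liquid transition.
* **creep** — under constant applied stress, compliance that keeps
  growing linearly at late times indicates fluidization; the yield stress
  is the lowest applied stress whose creep curve fluidizes.

Replicate yield estimates are summarized as mean ± sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np


@dataclass
class AmplitudeSweep:
    """Oscillatory amplitude-sweep curves (strain in %, stresses/moduli in Pa)."""

    strain_pct: np.ndarray
    stress_pa: np.ndarray
    gprime_pa: np.ndarray | None = None
    gdouble_pa: np.ndarray | None = None
    omega: float = 1.0  # rad/s

    def __post_init__(self) -> None:
        self.strain_pct = np.asarray(self.strain_pct, float)
        self.stress_pa = np.asarray(self.stress_pa, float)
        if np.any(np.diff(self.strain_pct) <= 0):
            raise ValueError("strain grid must be strictly increasing")
        if np.any(self.stress_pa <= 0):
            raise ValueError("stresses must be positive")
        for name in ("gprime_pa", "gdouble_pa"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, float))


@dataclass
class CreepSet:
    """Creep compliance records J(t) per applied stress (Pa -> 1/Pa)."""

    time_s: np.ndarray
    compliance: Mapping[float, np.ndarray]

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time vector must be strictly increasing")
        for s, J in self.compliance.items():
            if np.any(np.asarray(J) < 0):
                raise ValueError(f"compliance at {s} Pa must be nonnegative")


@dataclass
class YieldEstimate:
    """A yield-stress estimate plus the method and fit metadata behind it."""

    tau_yield: float | None
    method: str
    metadata: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return self.tau_yield is not None


def find_crossover(sweep: AmplitudeSweep) -> tuple[float, float] | None:
    """First G'/G'' crossover, log-log interpolated; None when absent.

    Requires G' > G'' at the low-strain end. An exact grid-point equality
    returns that grid point.
    """
    if sweep.gprime_pa is None or sweep.gdouble_pa is None:
        raise ValueError("sweep carries no moduli")
    gp, gpp, gam = sweep.gprime_pa, sweep.gdouble_pa, sweep.strain_pct
    if not gp[0] > gpp[0]:
        return None
    diff = gp - gpp
    eq = np.flatnonzero(diff == 0)
    flip = np.flatnonzero((diff[:-1] > 0) & (diff[1:] < 0))
    if len(eq) and (not len(flip) or eq[0] <= flip[0]):
        k = eq[0]
        return float(gam[k]), float(gp[k])
    if not len(flip):
        return None
    k = flip[0]
    # linear interpolation of log(G'/G'') vs log(strain)
    lg = np.log(gam[k : k + 2])
    ld = np.log(gp[k : k + 2]) - np.log(gpp[k : k + 2])
    t = ld[0] / (ld[0] - ld[1])
    lx = lg[0] + t * (lg[1] - lg[0])
    lmod = np.log(gp[k]) + t * (np.log(gp[k + 1]) - np.log(gp[k]))
    return float(np.exp(lx)), float(np.exp(lmod))


def _powerlaw_fit(gamma: np.ndarray, sigma: np.ndarray) -> tuple[float, float]:
    """Least squares in log-log space; returns (prefactor a, exponent b)."""
    b, loga = np.polyfit(np.log(gamma), np.log(sigma), 1)
    return float(np.exp(loga)), float(b)


def default_region_rule(sweep: AmplitudeSweep) -> tuple[np.ndarray, np.ndarray]:
    """Default fit windows: below = strain under half the G'/G'' crossover
    strain (or the lowest decade when no moduli/crossover are available);
    above = the top decade of strain."""
    gam = sweep.strain_pct
    cross = None
    if sweep.gprime_pa is not None and sweep.gdouble_pa is not None:
        cross = find_crossover(sweep)
    if cross is not None:
        below = gam < cross[0] / 2.0
    else:
        below = gam <= gam[0] * 10.0
    above = gam >= gam[-1] / 10.0
    return below, above


def yield_from_intersection(
    sweep: AmplitudeSweep,
    region_rule: Callable[[AmplitudeSweep], tuple[np.ndarray, np.ndarray]] | None = None,
) -> YieldEstimate:
    """Yield stress as the intersection of below/above power-law fits.

    Fits sigma = a * gamma^b by least squares in log-log space on each
    region; the intersection is gamma* = (a2/a1)^(1/(b1-b2)) with
    tau_yield = a1 * gamma*^b1. Requires the below-yield branch to be
    steeper (b1 > b2) and at least 4 points per region.
    """
    rule = region_rule or default_region_rule
    below, above = rule(sweep)
    below = np.asarray(below, bool)
    above = np.asarray(above, bool)
    if np.any(below & above):
        raise ValueError("fit regions must not overlap")
    if below.sum() < 4 or above.sum() < 4:
        raise ValueError("need at least 4 points in each fit region")
    gam, sig = sweep.strain_pct, sweep.stress_pa
    a1, b1 = _powerlaw_fit(gam[below], sig[below])
    a2, b2 = _powerlaw_fit(gam[above], sig[above])
    if b1 <= b2:
        raise ValueError(
            "no flattening above yield (below-exponent must exceed above-exponent)"
        )
    gamma_star = (a2 / a1) ** (1.0 / (b1 - b2))
    tau = a1 * gamma_star**b1
    return YieldEstimate(
        float(tau),
        "intersection",
        {
            "gamma_yield_pct": float(gamma_star),
            "below_fit": (a1, b1),
            "above_fit": (a2, b2),
        },
    )


def yield_from_creep(
    creep: CreepSet,
    tail_fraction: float = 0.5,
    slope_threshold: float | None = None,
    r2_min: float = 0.98,
) -> YieldEstimate:
    """Yield stress as the lowest applied stress whose creep curve fluidizes.

    For each applied stress a line is fitted to J(t) over the final
    ``tail_fraction`` of the record; the curve is classified fluidized
    when the fitted slope exceeds ``slope_threshold`` and the tail fit has
    R² >= ``r2_min`` (late-time linear growth). When no threshold is
    given, 10x the median tail slope of the sub-median-stress curves is
    used.
    """
    stresses = sorted(creep.compliance)
    if len(stresses) < 2:
        raise ValueError("need at least 2 applied stresses")
    t = creep.time_s
    n_tail = max(3, int(round(tail_fraction * len(t))))
    slopes, r2s = {}, {}
    for s in stresses:
        J = np.asarray(creep.compliance[s], float)
        tt, JJ = t[-n_tail:], J[-n_tail:]
        slope, intercept = np.polyfit(tt, JJ, 1)
        resid = JJ - (slope * tt + intercept)
        ss_tot = np.sum((JJ - JJ.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
        slopes[s], r2s[s] = float(slope), float(r2)
    if slope_threshold is None:
        low = [slopes[s] for s in stresses[: max(1, len(stresses) // 2)]]
        slope_threshold = 10.0 * max(np.median(low), 1e-15)
    fluid = [
        s for s in stresses if slopes[s] > slope_threshold and r2s[s] >= r2_min
    ]
    meta = {"slopes": slopes, "r2": r2s, "slope_threshold": float(slope_threshold)}
    if not fluid:
        return YieldEstimate(None, "creep", {**meta, "fluidized": False})
    return YieldEstimate(float(min(fluid)), "creep", {**meta, "fluidized": True})


def summarize_yield(estimates) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of replicate yield stresses."""
    vals = np.asarray(list(estimates), float)
    if len(vals) < 2:
        raise ValueError("need at least 2 estimates for a mean ± SD summary")
    return float(vals.mean()), float(vals.std(ddof=1))
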