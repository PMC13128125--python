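"""Synthetic oscillatory amplitude sweeps and creep curves with known yield.

The amplitude sweep follows the two-regime power law observed for gut
content: stress grows as tau_y * (gamma/gamma_y)^b1 below the yield
strain and as tau_y * (gamma/gamma_y)^b2 above it, with b1 > b2 >= 0 so
the curve flattens past yield and the two branches meet exactly at
(gamma_y, tau_y). Storage and loss moduli are generated as power laws
crossing at a configurable strain. Creep compliance follows a delayed
elastic rise J(t) = (1/G)(1 - exp(-t/t_r)) below the yield stress, with
an added steady-flow term t/eta once the applied stress reaches yield
(the fluidization signature: late-time linear growth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..rheology import AmplitudeSweep, CreepSet


@dataclass(frozen=True)
class SyntheticRheologyTruth:
    """Ground-truth rheological parameters of a generated dataset."""

    yield_stress: float  # tau_y, Pa
    yield_strain: float  # gamma_y, % strain
    below_exponent: float = 0.9  # b1
    above_exponent: float = 0.2  # b2
    crossover_strain: float | None = None  # % strain where G' meets G''
    creep_stresses: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 50.0)

    def __post_init__(self) -> None:
        if self.yield_stress <= 0 or self.yield_strain <= 0:
            raise ValueError("yield_stress and yield_strain must be positive")
        if not self.below_exponent > self.above_exponent >= 0:
            raise ValueError("need below_exponent > above_exponent >= 0")

    @property
    def crossover(self) -> float:
        """Crossover strain (%); defaults to twice the yield strain, the
        solid-to-liquid transition sitting just past the yield point."""
        return (
            self.crossover_strain
            if self.crossover_strain is not None
            else 2.0 * self.yield_strain
        )


def sweep_stress(truth: SyntheticRheologyTruth, strain: np.ndarray) -> np.ndarray:
    """Noiseless two-branch power-law stress at strain (%)."""
    strain = np.asarray(strain, float)
    rel = strain / truth.yield_strain
    return truth.yield_stress * np.where(
        strain < truth.yield_strain,
        rel**truth.below_exponent,
        rel**truth.above_exponent,
    )


def gen_rheology_dataset(
    truth: SyntheticRheologyTruth,
    n_points_per_decade: int = 10,
    noise_rel: float = 0.0,
    seed: int = 0,
    modulus_scale: float = 100.0,
    gprime_exponent: float = -0.5,
    gdouble_exponent: float = -0.2,
    creep_modulus: float = 500.0,
    creep_retardation: float = 20.0,
    creep_viscosity: float = 2000.0,
    creep_duration: float = 300.0,
    creep_n_points: int = 100,
) -> tuple[AmplitudeSweep, CreepSet]:
    """Generate an amplitude sweep and a creep set from known truth.

    The strain grid is log-spaced over 0.1-1000% (4 decades), matching a
    rheometer strain ramp. G' and G'' are power laws
    G'(g) = modulus_scale*(g/g_x)^e1, G''(g) = modulus_scale*(g/g_x)^e2
    with e1 < e2, equal at the crossover strain g_x. Multiplicative noise
    (1 + noise_rel * N(0,1)) is applied to stress and moduli.
    """
    rng = np.random.default_rng(seed)
    strain = np.logspace(-1, 3, 4 * n_points_per_decade + 1)
    stress = sweep_stress(truth, strain)
    gx = truth.crossover
    gp = modulus_scale * (strain / gx) ** gprime_exponent
    gpp = modulus_scale * (strain / gx) ** gdouble_exponent
    if noise_rel > 0:
        stress = stress * (1 + noise_rel * rng.standard_normal(strain.shape))
        gp = gp * (1 + noise_rel * rng.standard_normal(strain.shape))
        gpp = gpp * (1 + noise_rel * rng.standard_normal(strain.shape))
    sweep = AmplitudeSweep(
        strain_pct=strain,
        stress_pa=np.abs(stress),
        gprime_pa=np.abs(gp),
        gdouble_pa=np.abs(gpp),
        omega=1.0,
    )

    t = np.linspace(0.0, creep_duration, creep_n_points + 1)[1:]
    curves: dict[float, np.ndarray] = {}
    for s in truth.creep_stresses:
        J = (1.0 / creep_modulus) * (1.0 - np.exp(-t / creep_retardation))
        if s >= truth.yield_stress:
            J = J + t / creep_viscosity
        if noise_rel > 0:
            J = np.abs(J * (1 + noise_rel * rng.standard_normal(t.shape)))
        curves[float(s)] = J
    creep = CreepSet(time_s=t, compliance=curves)
    return sweep, creep
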