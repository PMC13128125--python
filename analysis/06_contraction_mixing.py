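#!/usr/bin/env python
"""Contraction-mixing model: how deep can a gut contraction fluidize digesta?

Evaluates the Stokes-second-problem model with the measured digesta
parameters (yield stress 45 Pa, viscosity 2237 Pa·s, density 1250 kg/m³):
wall shear-stress amplitude versus contraction amplitude and frequency,
and the mixing depth D at which the decaying stress amplitude falls to
the yield stress. Writes the depth matrix and two figures under
results/stokes/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from gutspat import StokesParameters, depth_grid, wall_stress_amplitude
from gutspat.reference_data import (
    DIGESTA_DENSITY_KG_M3,
    DIGESTA_VISCOSITY_PA_S,
    DIGESTA_YIELD_STRESS_PA,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "stokes"
MATERIAL = dict(
    mu=DIGESTA_VISCOSITY_PA_S,
    rho=DIGESTA_DENSITY_KG_M3,
    tau_yield=DIGESTA_YIELD_STRESS_PA,
)
AMPLITUDES = np.linspace(0.005, 0.05, 46)  # m, illustrative contraction range
OMEGAS = np.array([0.5, 1.0, 2.0, 5.0])  # rad/s


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    D = depth_grid(AMPLITUDES, OMEGAS, **MATERIAL)
    table = pd.DataFrame(
        D, index=pd.Index(AMPLITUDES, name="amplitude_m"),
        columns=[f"omega_{w}_rad_s" for w in OMEGAS],
    )
    table.to_csv(OUT / "mixing_depth_m.csv")

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for j, w in enumerate(OMEGAS):
        wall = [
            wall_stress_amplitude(StokesParameters(A, w, **MATERIAL))
            for A in AMPLITUDES
        ]
        axes[0].plot(AMPLITUDES * 100, wall, label=f"ω = {w} rad/s")
        axes[1].plot(AMPLITUDES * 100, D[:, j] * 100, label=f"ω = {w} rad/s")
    axes[0].axhline(MATERIAL["tau_yield"], color="k", ls="--", lw=0.8,
                    label=f"yield {MATERIAL['tau_yield']:.0f} Pa")
    axes[0].set_xlabel("contraction amplitude A (cm)")
    axes[0].set_ylabel("wall stress amplitude (Pa)")
    axes[0].set_yscale("log")
    axes[0].legend(fontsize=8)
    axes[1].set_xlabel("contraction amplitude A (cm)")
    axes[1].set_ylabel("mixing depth D (cm)")
    axes[1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(OUT / "mixing_depth.png", dpi=150)

    reached = table[table.sum(axis=1) > 0]
    print(f"depth matrix: {table.shape[0]} amplitudes x {table.shape[1]} frequencies")
    print(f"max mixing depth: {D.max()*100:.1f} cm "
          f"(A = {AMPLITUDES[np.unravel_index(D.argmax(), D.shape)[0]]*100:.0f} cm, "
          f"ω = {OMEGAS[np.unravel_index(D.argmax(), D.shape)[1]]} rad/s)")
    print(f"first amplitude reaching yield at ω = 1 rad/s: "
          f"{reached.index[reached['omega_1.0_rad_s'] > 0][0]*100:.1f} cm"
          if (table['omega_1.0_rad_s'] > 0).any() else "yield never reached at 1 rad/s")
    print(f"\nwrote depth matrix and figures to {OUT}")


if __name__ == "__main__":
    main()
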