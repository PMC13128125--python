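"""Reported per-sample measurements bundled for the summary analyses.

These are the published measurement values for gut-content material
properties that parameterize the contraction-mixing model and the yield
summaries; they are inputs to the analyses here, not outputs.
"""

# Per-sample yield stresses of mouse cecum content from power-law
# intersection on oscillatory amplitude sweeps (Pa), samples 1-5.
MOUSE_OSCILLATORY_YIELDS_PA = (47.79, 50.13, 39.66, 36.25, 58.21)

# Yield stresses of three independent mouse cecum content samples from
# creep fluidization (Pa).
MOUSE_CREEP_YIELDS_PA = (40.0, 20.0, 45.0)

# Per-sample yield stresses of human ileal effluent, power-law
# intersection (Pa), samples 1-4.
HUMAN_ILEAL_YIELDS_PA = (0.03, 0.44, 0.50, 0.03)

# Digesta density replicates from simultaneous weight/volume measurement
# (g/ml); their mean, in kg/m³ at three significant figures, is the
# density used by the contraction-mixing model.
DIGESTA_DENSITY_REPLICATES_G_ML = (1.16, 1.29, 1.31)

# Contraction-mixing model material parameters.
DIGESTA_YIELD_STRESS_PA = 45.0
DIGESTA_VISCOSITY_PA_S = 2237.0
DIGESTA_DENSITY_KG_M3 = 1250.0
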