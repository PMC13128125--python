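"""Small unit-conversion helpers (µm <-> m, percent <-> fraction, g/ml -> kg/m³)."""

from __future__ import annotations

import numpy as np


def um_to_m(x):
    return np.asarray(x, float) * 1e-6


def m_to_um(x):
    return np.asarray(x, float) * 1e6


def pct_to_fraction(x):
    return np.asarray(x, float) / 100.0


def fraction_to_pct(x):
    return np.asarray(x, float) * 100.0


def g_per_ml_to_kg_per_m3(x):
    return np.asarray(x, float) * 1000.0


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))
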