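"""Dirichlet-sampled per-site relative-abundance tables.

Each sample is a draw from Dirichlet(concentration * mean_composition),
the simplest compositional noise model with a single precision knob: as
the concentration grows, samples converge to the site's mean composition.
Tables start at the relative-abundance level (no sequencing simulation).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def gen_abundance_table(
    site_profiles: Mapping[str, Mapping[str, float] | Sequence[float]],
    concentration: float,
    n_per_site: int,
    seed: int = 0,
    taxa: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Sample ``n_per_site`` relative-abundance profiles for each site.

    ``site_profiles`` maps a site label (e.g., "base", "tip") to a mean
    composition over a shared taxon set; compositions must sum to 1 within
    1e-9. Returns a DataFrame with one row per sample, taxon columns, and
    metadata columns ``site`` and ``sample_id``; taxon rows sum to 1.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)

    profiles: dict[str, np.ndarray] = {}
    for site, comp in site_profiles.items():
        if isinstance(comp, Mapping):
            if taxa is None:
                taxa = list(comp.keys())
            vec = np.array([comp.get(t, 0.0) for t in taxa], float)
        else:
            vec = np.asarray(comp, float)
            if taxa is None:
                taxa = [f"taxon_{i}" for i in range(len(vec))]
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError(f"mean composition for site {site!r} must sum to 1")
        if np.any(vec < 0):
            raise ValueError("mean compositions must be nonnegative")
        profiles[site] = vec

    rows, sites, ids = [], [], []
    for site, vec in profiles.items():
        # Dirichlet with exact zeros in alpha: sample the support, keep zeros.
        support = vec > 0
        alpha = concentration * vec[support]
        draws = rng.dirichlet(alpha, size=n_per_site)
        for k in range(n_per_site):
            full = np.zeros_like(vec)
            full[support] = draws[k]
            rows.append(full / full.sum())
            sites.append(site)
            ids.append(f"{site}_{k}")
    df = pd.DataFrame(rows, columns=list(taxa))
    df.insert(0, "sample_id", ids)
    df.insert(1, "site", sites)
    return df
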