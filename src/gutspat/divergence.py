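"""Jensen-Shannon divergence between relative-abundance profiles.

A sample's relative abundances form a probability distribution P over the
taxon set B. For two samples P and Q with mixture M = (P + Q)/2,

    JSD(P, Q) = 1/2 D_KL(P || M) + 1/2 D_KL(Q || M),
    D_KL(P || M) = sum_b P(b) log(P(b) / M(b)),   0 log(0/..) := 0.

JSD is symmetric and bounded by log 2 (natural log, the default base;
base 2 gives the bound 1). Site comparisons aggregate all within-base,
within-tip, and base-to-tip pair divergences and test differences with a
one-sided Mann-Whitney U test whose direction must be stated explicitly.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def _as_prob(p, taxa: Sequence[str] | None = None) -> np.ndarray:
    if isinstance(p, Mapping):
        keys = taxa if taxa is not None else list(p.keys())
        vec = np.array([p.get(k, 0.0) for k in keys], float)
    else:
        vec = np.asarray(p, float)
    if np.any(vec < 0):
        raise ValueError("probabilities must be nonnegative")
    if abs(vec.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1 within 1e-9")
    return vec


def kl_divergence(p: np.ndarray, m: np.ndarray, base: float | str = "e") -> float:
    """D_KL(p || m) with the 0 log 0 convention."""
    mask = p > 0
    val = float(np.sum(p[mask] * np.log(p[mask] / m[mask])))
    return val / np.log(2.0) if base == 2 else val


def jsd(p, q, base: float | str = "e", taxa: Sequence[str] | None = None) -> float:
    """Jensen-Shannon divergence between two profiles (nats by default).

    Dict inputs are outer-joined over their union of taxa with zeros.
    """
    if isinstance(p, Mapping) and isinstance(q, Mapping) and taxa is None:
        taxa = sorted(set(p) | set(q))
    pv = _as_prob(p, taxa)
    qv = _as_prob(q, taxa)
    if pv.shape != qv.shape:
        raise ValueError("profiles must share a taxon set")
    m = 0.5 * (pv + qv)
    return 0.5 * kl_divergence(pv, m, base) + 0.5 * kl_divergence(qv, m, base)


def pairwise_jsd(table: pd.DataFrame, base: float | str = "e") -> pd.DataFrame:
    """Symmetric JSD matrix over the rows of an abundance table.

    Non-numeric (metadata) columns are ignored; the index labels samples.
    """
    numeric = table.select_dtypes(include=[np.number])
    if len(numeric) < 2:
        raise ValueError("need at least 2 samples")
    vals = numeric.to_numpy(float)
    n = len(vals)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = jsd(vals[i], vals[j], base)
    return pd.DataFrame(out, index=table.index, columns=table.index)


def aggregate_families(
    table: pd.DataFrame, family_map: Mapping[str, str]
) -> pd.DataFrame:
    """Group taxon columns into families by summation (metadata preserved)."""
    numeric = table.select_dtypes(include=[np.number])
    meta = table.drop(columns=numeric.columns)
    fam = numeric.T.groupby(
        numeric.columns.map(lambda c: family_map.get(c, c))
    ).sum().T
    return pd.concat([meta, fam], axis=1)


def grouped_comparison(
    matrix: pd.DataFrame,
    site_labels: Sequence[str],
    alternative: str,
) -> dict:
    """Base/base, tip/tip, base/tip divergence groups + one-sided U tests.

    ``alternative`` names the tested direction for every comparison and is
    required: "less" tests whether the first listed group is stochastically
    smaller than the second. Comparisons made: within_base vs between,
    within_tip vs between, within_base vs within_tip. A site with fewer
    than 2 samples yields an empty within-group list and skipped tests.
    """
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater' (no default)")
    labels = np.asarray(site_labels)
    if len(labels) != len(matrix):
        raise ValueError("one site label per sample is required")
    vals = matrix.to_numpy(float)
    idx_base = np.flatnonzero(labels == "base")
    idx_tip = np.flatnonzero(labels == "tip")

    def within(idx):
        return [vals[a, b] for k, a in enumerate(idx) for b in idx[k + 1 :]]

    groups = {
        "base/base": within(idx_base),
        "tip/tip": within(idx_tip),
        "base/tip": [vals[a, b] for a in idx_base for b in idx_tip],
    }

    tests = {}
    comparisons = [
        ("base/base", "base/tip"),
        ("tip/tip", "base/tip"),
        ("base/base", "tip/tip"),
    ]
    import warnings

    for a, b in comparisons:
        if len(groups[a]) < 1 or len(groups[b]) < 1:
            warnings.warn(f"skipping U test {a} vs {b}: empty group", stacklevel=2)
            continue
        pooled = np.concatenate([groups[a], groups[b]])
        if np.all(pooled == pooled[0]):
            # degenerate: the statistic is permutation-invariant, no evidence
            tests[f"{a} vs {b}"] = 1.0
            continue
        method = "exact" if max(len(groups[a]), len(groups[b])) <= 20 else "asymptotic"
        res = stats.mannwhitneyu(
            groups[a], groups[b], alternative=alternative, method=method
        )
        tests[f"{a} vs {b}"] = float(res.pvalue)
    return {"groups": groups, "p_values": tests, "alternative": alternative}
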