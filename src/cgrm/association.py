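"""Overlap and association statistics among regulator target sets.

Four statistics quantify how two gene sets relate: the Jaccard index
|A∩B|/|A∪B|, the Simpson (overlap) index |A∩B|/min(|A|,|B|), a
hypergeometric over-representation p-value P(X >= k), and a connection
specificity index (CSI) that discounts a pairwise similarity by how many
third parties are almost as similar to either member of the pair.
Enrichment tables carry Benjamini-Hochberg q-values per comparison family,
reported alongside (never replacing) the raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection


@dataclass
class OverlapStats:
    set_a_name: str
    set_b_name: str
    n_a: int
    n_b: int
    n_overlap: int
    universe_n: int
    jaccard: float
    simpson: float
    hypergeom_p: float
    csi: float | None = None

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_a, self.n_b):
            raise ValueError("overlap exceeds the smaller set")
        if not (0 < self.hypergeom_p <= 1):
            raise ValueError("hypergeometric p must lie in (0, 1]")


def jaccard(a: set, b: set) -> float:
    """|A∩B| / |A∪B|; 0 when both sets are empty."""
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def simpson(a: set, b: set) -> float:
    """|A∩B| / min(|A|, |B|); requires at least one non-empty set."""
    if not a and not b:
        raise ValueError("Simpson index undefined for two empty sets")
    smaller = min(len(a), len(b))
    return len(a & b) / smaller if smaller else 0.0


def hypergeom_overrep(k: int, n_a: int, n_b: int, universe: int) -> float:
    """Over-representation tail P(X >= k), X ~ Hypergeom(universe, n_a, n_b).

    Computed in log space via the survival function; k = 0 returns 1.
    """
    if not (0 <= k <= min(n_a, n_b)):
        raise ValueError(f"overlap k={k} outside [0, min({n_a}, {n_b})]")
    if max(n_a, n_b) > universe:
        raise ValueError("set sizes exceed the universe")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, universe, n_a, n_b))
    return min(max(p, np.finfo(float).tiny), 1.0)


def csi(
    sim: np.ndarray,
    a: int,
    b: int,
    gap: float = 0.05,
) -> float:
    """Connection specificity index of pair (a, b) within a similarity matrix.

    The fraction of third parties c (c != a, b) whose similarity to both a
    and b falls below ``sim[a, b] - gap``: 1 when the a-b connection is
    uniquely strong, 0 when every third party is (almost) as similar.
    """
    sim = np.asarray(sim, dtype=float)
    m = sim.shape[0]
    if sim.shape != (m, m):
        raise ValueError("similarity matrix must be square")
    if m < 3:
        raise ValueError("CSI needs at least 3 regulators")
    if not np.allclose(sim, sim.T, atol=1e-12):
        raise ValueError("similarity matrix must be symmetric")
    thresh = sim[a, b] - gap
    others = [c for c in range(m) if c not in (a, b)]
    n_specific = sum(1 for c in others if sim[a, c] < thresh and sim[b, c] < thresh)
    return n_specific / (m - 2)


def similarity_matrix(
    sets: Mapping[str, set], metric: str = "jaccard"
) -> tuple[list[str], np.ndarray]:
    """Pairwise target-set similarity matrix (substrate for CSI)."""
    names = sorted(sets)
    m = len(names)
    sim = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            if metric == "jaccard":
                s = jaccard(sets[names[i]], sets[names[j]])
            elif metric == "simpson":
                s = simpson(sets[names[i]], sets[names[j]])
            else:
                raise ValueError(f"unknown similarity metric {metric!r}")
            sim[i, j] = sim[j, i] = s
    return names, sim


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def overlap_stats(
    name_a: str,
    a: set,
    name_b: str,
    b: set,
    universe: set,
    csi_value: float | None = None,
) -> OverlapStats:
    k = len(a & b)
    return OverlapStats(
        set_a_name=name_a,
        set_b_name=name_b,
        n_a=len(a),
        n_b=len(b),
        n_overlap=k,
        universe_n=len(universe),
        jaccard=jaccard(a, b),
        simpson=simpson(a, b) if (a or b) else 0.0,
        hypergeom_p=hypergeom_overrep(k, len(a), len(b), len(universe)),
        csi=csi_value,
    )


def target_set_enrichment(
    target_sets: Mapping[str, set],
    reference_sets: GeneSetCollection,
    universe: set,
    gap: float = 0.05,
) -> pd.DataFrame:
    """All pairwise overlap statistics between target sets and reference sets.

    BH q-values are computed within each target-set family (one target set
    against the whole reference collection). CSI is attached only for
    comparisons within the target-set collection itself when it has >= 3
    members (it needs a similarity context).
    """
    for name, s in {**dict(target_sets), **reference_sets.sets}.items():
        extra = s - universe
        if extra:
            raise ValueError(
                f"set {name!r} has {len(extra)} members outside the universe, "
                f"e.g. {sorted(extra)[:3]}"
            )
    rows = []
    for tname in sorted(target_sets):
        family = []
        for rname in reference_sets.names():
            st = overlap_stats(tname, target_sets[tname], rname,
                               reference_sets[rname], universe)
            family.append(st)
        qs = bh_adjust([st.hypergeom_p for st in family])
        for st, q in zip(family, qs):
            rows.append(
                (st.set_a_name, st.set_b_name, st.n_a, st.n_b, st.n_overlap,
                 st.universe_n, st.jaccard, st.simpson, st.hypergeom_p, float(q))
            )
    return pd.DataFrame(
        rows,
        columns=["target_set", "reference_set", "n_a", "n_b", "n_overlap",
                 "universe_n", "jaccard", "simpson", "p", "q"],
    )
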