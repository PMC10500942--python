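"""Regulator-target interaction inference by constrained factorization.

Expression is approximated as X ~= Y Z (Frobenius loss), where each row of
Z is a regulator's activity profile summarized (median by default) from the
expression of its known targets, and Y holds non-negative regulator->gene
interaction strengths (0 = non-interaction). Y is obtained per gene by
non-negative least squares; empirical significance of each strength comes
from permutation tests that re-solve the factorization after shuffling the
sample labels of every gene row independently (1000 permutations by
default), with add-one smoothing so p is never exactly zero:

    p[g, r] = (1 + #{permuted strength >= observed}) / (n_perm + 1)

Because the targets that build a regulator's Z row are not excluded from X,
those (gene, regulator) entries carry a circularity flag in the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .deg import DEGTable
from .io import ExpressionSeries, RegulatorTargetMap

logger = logging.getLogger(__name__)

SUMMARY_METHODS = ("median", "mean", "trimmed_mean")


@dataclass
class ActivityProfile:
    """Regulator activity matrix Z (regulators x samples)."""

    regulator_ids: list[str]
    sample_ids: list
    z_values: np.ndarray
    summary_method: str = "median"
    n_targets_used: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        if self.z_values.shape != (len(self.regulator_ids), len(self.sample_ids)):
            raise ValueError("z_values shape does not match id lists")
        if self.summary_method not in SUMMARY_METHODS:
            raise ValueError(f"unknown summary method {self.summary_method!r}")


@dataclass
class InteractionResult:
    """Non-negative interaction strengths with empirical p-values."""

    gene_ids: list[str]
    regulator_ids: list[str]
    strengths: np.ndarray
    p_values: np.ndarray
    direction_context: str  # DEG group the X submatrix came from: up or down
    circular: np.ndarray | None = None  # True where gene fed the regulator's Z row
    residual: float = float("nan")

    def __post_init__(self) -> None:
        self.strengths = np.asarray(self.strengths, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        shape = (len(self.gene_ids), len(self.regulator_ids))
        if self.strengths.shape != shape or self.p_values.shape != shape:
            raise ValueError("matrix shapes do not match id lists")
        if np.any(self.strengths < 0):
            raise ValueError("strengths must be non-negative")
        if np.any((self.p_values <= 0) | (self.p_values > 1)):
            raise ValueError("p-values must lie in (0, 1]")
        if self.circular is None:
            self.circular = np.zeros(shape, dtype=bool)

    def to_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.gene_ids):
            for j, r in enumerate(self.regulator_ids):
                rows.append(
                    (g, r, self.strengths[i, j], self.p_values[i, j],
                     bool(self.p_values[i, j] < alpha), bool(self.circular[i, j]),
                     self.direction_context)
                )
        return pd.DataFrame(
            rows,
            columns=["gene", "regulator", "strength", "p", "significant",
                     "circular_flag", "direction"],
        )


LOG_PSEUDOCOUNT = 1.0


def build_activity_profile(
    expr: ExpressionSeries,
    maps: Sequence[RegulatorTargetMap],
    method: str = "median",
    log_scale: bool = False,
) -> ActivityProfile:
    """Summarize each regulator's measured targets into a Z row.

    With ``log_scale`` the summary runs on log2(x + 1) values, the scale on
    which multiplicative regulation is additive.
    """
    if method not in SUMMARY_METHODS:
        raise ValueError(f"unknown summary method {method!r}")
    lin = expr.to_linear()
    values = np.log2(lin.values + LOG_PSEUDOCOUNT) if log_scale else lin.values
    index = {g: i for i, g in enumerate(lin.gene_ids)}
    z = np.empty((len(maps), lin.n_time_points))
    n_used: dict[str, int] = {}
    for i, m in enumerate(maps):
        rows = [values[index[t]] for t in sorted(m.target_gene_ids) if t in lin]
        if not rows:
            raise ValueError(
                f"regulator {m.regulator_id!r} has no measured targets in the "
                "expression matrix"
            )
        mat = np.asarray(rows)
        if method == "median":
            z[i] = np.median(mat, axis=0)
        elif method == "mean":
            z[i] = mat.mean(axis=0)
        else:  # trimmed_mean, 10% each tail
            z[i] = stats.trim_mean(mat, 0.1, axis=0)
        n_used[m.regulator_id] = len(rows)
    return ActivityProfile(
        [m.regulator_id for m in maps], list(lin.time_points), z,
        summary_method=method, n_targets_used=n_used,
    )


def _solve_matrix(x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-gene NNLS: strengths[g] = argmin_{y>=0} ||x[g] - y @ z||^2."""
    zt = z.T  # samples x regulators
    out = np.empty((x.shape[0], z.shape[0]))
    if z.shape[0] == 1:
        # closed form: projection onto the single activity row, clamped at 0
        denom = float(zt[:, 0] @ zt[:, 0])
        out[:, 0] = np.maximum(x @ zt[:, 0], 0.0) / denom if denom > 0 else 0.0
        return out
    for g in range(x.shape[0]):
        out[g], _ = optimize.nnls(zt, x[g])
    return out


def solve_interaction_strengths(
    x: np.ndarray | ExpressionSeries, z: ActivityProfile | np.ndarray
) -> tuple[np.ndarray, float]:
    """Solve the non-negative factorization X ~= Y Z for Y.

    Returns the (genes x regulators) strength matrix and the Frobenius
    residual ||X - Y Z||.
    """
    if isinstance(x, ExpressionSeries):
        xs = x.to_linear().values
        samples = list(x.time_points)
    else:
        xs = np.asarray(x, dtype=float)
        samples = None
    zm = z.z_values if isinstance(z, ActivityProfile) else np.asarray(z, dtype=float)
    if isinstance(z, ActivityProfile) and samples is not None:
        if list(z.sample_ids) != samples:
            raise ValueError("sample columns of X and Z are not aligned")
    if xs.shape[1] != zm.shape[1]:
        raise ValueError(
            f"sample mismatch: X has {xs.shape[1]} columns, Z has {zm.shape[1]}"
        )
    y = _solve_matrix(xs, zm)
    residual = float(np.linalg.norm(xs - y @ zm))
    return y, residual


def _permuted_rows(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle the sample labels of every gene row independently."""
    idx = rng.random(x.shape).argsort(axis=1)
    return np.take_along_axis(x, idx, axis=1)


def permutation_test(
    x: np.ndarray,
    z: np.ndarray,
    observed: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Empirical p-values for observed strengths under within-gene shuffles.

    Each permutation independently shuffles the sample labels of every gene
    row of X (preserving each gene's value distribution, breaking temporal
    alignment with Z) and re-solves the NNLS. Permutation streams are keyed
    by (seed, permutation index), so results do not depend on execution
    order or thread count.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    count = np.zeros_like(observed, dtype=np.int64)
    for b in range(n_perm):
        rng = np.random.Generator(np.random.Philox(key=[seed, b]))
        perm = _solve_matrix(_permuted_rows(x, rng), z)
        count += perm >= observed
    return (1.0 + count) / (n_perm + 1.0)


def rca_analysis(
    expr: ExpressionSeries,
    maps: Sequence[RegulatorTargetMap],
    gene_ids: Sequence[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    z_method: str = "median",
    log_scale: bool = True,
    augment: bool = True,
    z_expr: ExpressionSeries | None = None,
    direction_context: str = "up",
) -> InteractionResult:
    """One complete factorization analysis with permutation significance.

    Production defaults reflect two facts about expression data: regulation
    acts multiplicatively, so the factorization runs on log2(x + 1) values
    (``log_scale``); and all genes share a developmental trend plus a
    gene-specific level, so with ``augment`` the activity matrix gains a
    background row (the median profile over all analysed genes) and a
    constant row, whose coefficients absorb trend and level. Regulator
    strengths and p-values then measure regulator-specific modulation.
    ``gene_ids`` restricts the analysed genes (e.g. one DEG direction);
    ``z_expr`` optionally supplies a different matrix for building Z.
    """
    if not maps:
        raise ValueError("no regulator-target maps to run on")
    profile = build_activity_profile(
        z_expr if z_expr is not None else expr, maps,
        method=z_method, log_scale=log_scale,
    )
    lin = expr.to_linear()
    genes = list(gene_ids) if gene_ids is not None else list(lin.gene_ids)
    sub = lin.subset(genes)
    x = np.log2(sub.values + LOG_PSEUDOCOUNT) if log_scale else sub.values
    design = profile.z_values
    if augment:
        design = np.vstack([
            design,
            np.median(x, axis=0),        # shared trend
            np.ones(x.shape[1]),         # gene-specific level
        ])
    strengths_full = _solve_matrix(x, design)
    residual = float(np.linalg.norm(x - strengths_full @ design))
    p_full = permutation_test(x, design, strengths_full, n_perm=n_perm, seed=seed)
    n_reg = len(maps)
    circular = np.array(
        [[g in m.target_gene_ids for m in maps] for g in genes], dtype=bool
    )
    return InteractionResult(
        gene_ids=genes,
        regulator_ids=[m.regulator_id for m in maps],
        strengths=strengths_full[:, :n_reg],
        p_values=p_full[:, :n_reg],
        direction_context=direction_context,
        circular=circular,
        residual=residual,
    )


def run_rca(
    expr: ExpressionSeries,
    degs: DEGTable,
    maps: Sequence[RegulatorTargetMap],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    z_method: str = "median",
    z_from_degs: bool = False,
    log_scale: bool = True,
    augment: bool = True,
    regulator_classes: Sequence[str] | None = None,
) -> dict[str, InteractionResult]:
    """Run the factorization separately on up- and down-regulated DEGs.

    Returns a dict with keys 'up' and 'down'; a direction with fewer than
    two genes is skipped with a warning and omitted from the result. Z is
    built from all measured targets unless ``z_from_degs`` restricts it to
    DEGs. ``regulator_classes`` optionally restricts the regulator maps
    (e.g. to miRNA/lncRNA only); see :func:`rca_analysis` for the
    ``log_scale`` / ``augment`` design choices.
    """
    if regulator_classes is not None:
        maps = [m for m in maps if m.regulator_class in regulator_classes]
    if not maps:
        raise ValueError("no regulator-target maps to run on")
    z_expr = None
    if z_from_degs:
        z_expr = expr.subset([g for g in degs.gene_ids if g in expr])
    results: dict[str, InteractionResult] = {}
    for direction in ("up", "down"):
        genes = [g for g in degs.genes(direction) if g in expr]
        if len(genes) < 2:
            logger.warning(
                "direction %r has %d gene(s); skipped", direction, len(genes)
            )
            continue
        results[direction] = rca_analysis(
            expr, maps, gene_ids=genes, n_perm=n_perm, seed=seed,
            z_method=z_method, log_scale=log_scale, augment=augment,
            z_expr=z_expr, direction_context=direction,
        )
    return results
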