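"""TF regulatory-logic inference from transcription kinetics.

A target gene's transcription rate is modelled as a saturating function of
the combined binding occupancy Y of one or two TFs acting under a Boolean
logic (AND / OR / NOT):

    I_s(t) = I_max * (1 - exp(-k_b * Y(t - T_m) / I_max))

which is the closed form of the alternating series
``I_max * sum_{n>=1} (-1)^(n+1) (k_b/I_max)^n Y^n / n!``. ``I_max`` is the
initial (maximal) transcription rate, ``k_b`` the TF activation strength
and ``T_m`` an integer regulation delay in time-point steps (default 1).

For each candidate logic the observed rate proxy — a first-order finite
difference of the expression series, optionally plus a linear decay term —
is regressed on the model rate by bounded nonlinear least squares; candidate
logics are then scored with normalized AICc weights, so per-gene confidences
sum to one and a dominant logic approaches confidence 1.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .deg import DEGTable
from .io import BindingMatrix, ExpressionSeries

logger = logging.getLogger(__name__)

OPERATORS = ("SINGLE", "AND", "OR", "NOT")
_OP_SYMBOL = {"AND": "&", "OR": "|", "NOT": ">"}
_SYMBOL_OP = {v: k for k, v in _OP_SYMBOL.items()}

#: residual floor per observation, guards log(0) in AICc for exact fits
RSS_FLOOR_PER_OBS = 1e-24


@dataclass(frozen=True)
class TFLogic:
    """A Boolean logic over one or two TFs.

    AND/OR are commutative and canonicalized lexicographically; NOT
    (``TF1 > TF2``: TF1 activates, TF2 represses) is order-sensitive.
    """

    operator: str
    operands: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.operator not in OPERATORS:
            raise ValueError(f"unknown operator {self.operator!r}")
        ops = tuple(self.operands)
        n_expected = 1 if self.operator == "SINGLE" else 2
        if len(ops) != n_expected:
            raise ValueError(
                f"{self.operator} logic takes {n_expected} operand(s), got {len(ops)}"
            )
        if len(set(ops)) != len(ops):
            raise ValueError("logic operands must be distinct")
        if self.operator in ("AND", "OR"):
            ops = tuple(sorted(ops))
        object.__setattr__(self, "operands", ops)

    def __str__(self) -> str:
        if self.operator == "SINGLE":
            return self.operands[0]
        return f"{self.operands[0]} {_OP_SYMBOL[self.operator]} {self.operands[1]}"

    @classmethod
    def from_string(cls, text: str) -> "TFLogic":
        for sym, op in _SYMBOL_OP.items():
            if sym in text:
                a, b = (part.strip() for part in text.split(sym, 1))
                return cls(op, (a, b))
        return cls("SINGLE", (text.strip(),))


@dataclass
class KineticParams:
    i_max: float
    k_b: float
    t_m: int = 1

    def __post_init__(self) -> None:
        if not self.i_max > 0:
            raise ValueError("i_max must be > 0")
        if self.k_b < 0:
            raise ValueError("k_b must be >= 0")
        if self.t_m < 0 or int(self.t_m) != self.t_m:
            raise ValueError("t_m must be a non-negative integer")
        self.t_m = int(self.t_m)


@dataclass
class LogicFit:
    gene_id: str
    logic: TFLogic
    params: KineticParams
    rss: float
    n_obs: int
    confidence: float = float("nan")

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be >= 0")


def transcription_rate(
    params: KineticParams,
    y: float | np.ndarray,
    mode: str = "closed",
    n_terms: int = 30,
) -> float | np.ndarray:
    """Transcription rate at combined occupancy ``y``.

    ``mode='closed'`` evaluates ``I_max (1 - exp(-k_b y / I_max))``;
    ``mode='series'`` evaluates the partial sum of the alternating series
    to ``n_terms`` terms (kept as an independent cross-check of the closed
    form, not a production path).
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr < 0):
        raise ValueError("occupancy y must be >= 0")
    u = params.k_b * y_arr / params.i_max
    if mode == "closed":
        out = params.i_max * -np.expm1(-u)
    elif mode == "series":
        out = np.zeros_like(u)
        term = np.ones_like(u)
        for n in range(1, n_terms + 1):
            term = term * u / n  # u^n / n!
            out += (-1) ** (n + 1) * term
        out = params.i_max * out
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out if np.ndim(y) else float(out)


def combine_binding(
    logic: TFLogic,
    y1: float | np.ndarray,
    y2: float | np.ndarray | None = None,
) -> float | np.ndarray:
    """Combine per-TF occupancies under a logic into one occupancy in [0, 1].

    SINGLE -> y1; AND -> y1*y2; OR -> y1 + y2 - y1*y2 (probabilistic union);
    NOT (y1 activates, y2 represses) -> y1 * (1 - y2). The algebra agrees
    with the Boolean truth tables at {0, 1} and interpolates continuously.
    """
    y1 = np.asarray(y1, dtype=float)
    if np.any(y1 < 0) or np.any(y1 > 1):
        raise ValueError("occupancies must lie in [0, 1]")
    if logic.operator == "SINGLE":
        return y1
    if y2 is None:
        raise ValueError(f"{logic.operator} logic needs two operand occupancies")
    y2 = np.asarray(y2, dtype=float)
    if np.any(y2 < 0) or np.any(y2 > 1):
        raise ValueError("occupancies must lie in [0, 1]")
    if logic.operator == "AND":
        return y1 * y2
    if logic.operator == "OR":
        return y1 + y2 - y1 * y2
    return y1 * (1.0 - y2)  # NOT


def enumerate_logics(tf_ids: Sequence[str], max_pair_order: int = 2) -> list[TFLogic]:
    """All candidate logics over ``tf_ids``: singles, unordered AND/OR pairs,
    ordered NOT pairs; deterministic lexicographic order."""
    tfs = sorted(set(tf_ids))
    if not tfs:
        raise ValueError("need at least one TF")
    logics = [TFLogic("SINGLE", (t,)) for t in tfs]
    if max_pair_order >= 2:
        for a, b in itertools.combinations(tfs, 2):
            logics.append(TFLogic("AND", (a, b)))
            logics.append(TFLogic("OR", (a, b)))
        for a, b in itertools.permutations(tfs, 2):
            logics.append(TFLogic("NOT", (a, b)))
    logics.sort(key=lambda lg: (lg.operator != "SINGLE", str(lg)))
    return logics


def rate_proxy(
    values: np.ndarray, time_points: np.ndarray, decay: float = 0.0
) -> np.ndarray:
    """Observed transcription-rate proxy r(t_k) for k >= 1.

    First-order finite difference of expression plus an optional linear
    decay term: ``r_k = (E_k - E_{k-1}) / (t_k - t_{k-1}) + decay * E_k``.
    """
    dt = np.diff(time_points)
    return np.diff(values) / dt + decay * values[1:]


def _combined_series(
    logic: TFLogic, occupancy: Mapping[str, np.ndarray], n_time: int
) -> np.ndarray:
    series = []
    for tf in logic.operands:
        if tf not in occupancy:
            raise ValueError(f"missing occupancy for operand TF {tf!r}")
        y = np.asarray(occupancy[tf], dtype=float)
        y = np.full(n_time, float(y)) if y.ndim == 0 else y
        if y.shape != (n_time,):
            raise ValueError(f"occupancy series for {tf!r} has wrong length")
        series.append(y)
    return np.asarray(
        combine_binding(logic, *series)
        if len(series) > 1
        else combine_binding(logic, series[0])
    )


def fit_logic(
    expr_row: np.ndarray,
    time_points: np.ndarray,
    logic: TFLogic,
    occupancy: Mapping[str, np.ndarray | float],
    gene_id: str = "",
    t_m: int = 1,
    decay: float = 0.0,
    whiten: bool = True,
) -> LogicFit:
    """Fit (I_max, k_b) of the kinetic model for one gene under one logic.

    ``occupancy`` maps each operand TF to its occupancy series over the
    expression time grid (scalars are broadcast; values in [0, 1]).
    The observed rate proxy at index k is matched against the model rate
    evaluated at the lagged occupancy index ``k - t_m``; confidence is left
    unset (see :func:`logic_confidence`).

    Finite differencing makes the proxy's errors heteroscedastic (they
    scale with expression level under multiplicative measurement noise)
    and negatively correlated between adjacent points, so by default the
    residuals are whitened with the tridiagonal covariance this implies,
    estimated from the observed series; the reported RSS is then in
    whitened units, which cancel within a gene's candidate comparison.
    ``whiten=False`` falls back to ordinary least squares.
    """
    values = np.asarray(expr_row, dtype=float)
    time_points = np.asarray(time_points, dtype=float)
    if not (np.all(np.isfinite(values)) and np.all(np.isfinite(time_points))):
        raise ValueError("non-finite values in expression or time points")
    n_time = len(time_points)
    if values.shape != (n_time,):
        raise ValueError("expression row and time grid lengths differ")
    y_full = _combined_series(logic, occupancy, n_time)
    r_obs = rate_proxy(values, time_points, decay=decay)
    # usable rate indices: k >= max(1, t_m) so the lagged occupancy exists
    k_start = max(1, t_m)
    ks = np.arange(k_start, n_time)
    if len(ks) < 3:
        raise ValueError(
            f"only {len(ks)} usable time points after lag t_m={t_m}; need >= 3"
        )
    r = r_obs[ks - 1]
    y = y_full[ks - t_m]
    if whiten:
        # Var(r_k) ∝ E_k² + E_{k-1}²; Cov(r_k, r_{k+1}) ∝ -E_k² (shared term)
        dt = np.diff(time_points)
        sig2 = np.maximum(values, 1e-4) ** 2
        n = len(ks)
        cov = np.zeros((n, n))
        for a, ka in enumerate(ks):
            cov[a, a] = (sig2[ka] + sig2[ka - 1]) / dt[ka - 1] ** 2
            if a + 1 < n:
                cov[a, a + 1] = cov[a + 1, a] = -sig2[ka] / (dt[ka - 1] * dt[ka])
        l_inv = np.linalg.inv(np.linalg.cholesky(cov))
    else:
        l_inv = None

    def residuals(theta: np.ndarray) -> np.ndarray:
        i_max, k_b = theta
        raw = i_max * -np.expm1(-k_b * y / i_max) - r
        return raw if l_inv is None else l_inv @ raw

    def jac(theta: np.ndarray) -> np.ndarray:
        i_max, k_b = theta
        u = k_b * y / i_max
        e = np.exp(-u)
        j = np.column_stack([-np.expm1(-u) - u * e, y * e])
        return j if l_inv is None else l_inv @ j

    scale = max(float(np.max(np.abs(r))), 1e-6)
    y_max = max(float(np.max(y)), 1e-6)
    # in the unsaturated regime only k_b*y is identified and I_max drifts
    # upward on a flat likelihood; cap it at 1000x the observed rate scale
    i_max_ub = 1e3 * scale
    best = None
    for c in (0.1, 1.0, 10.0):
        x0 = np.array([scale, c * scale / y_max])
        sol = least_squares(
            residuals, x0, jac=jac, bounds=([1e-9, 0.0], [i_max_ub, np.inf]),
            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    i_max, k_b = best.x
    rss = float(np.sum(residuals(best.x) ** 2))
    return LogicFit(
        gene_id=gene_id,
        logic=logic,
        params=KineticParams(i_max=float(i_max), k_b=float(k_b), t_m=t_m),
        rss=rss,
        n_obs=len(ks),
    )


def logic_confidence(fits: Sequence[LogicFit]) -> list[LogicFit]:
    """Assign each candidate fit a confidence = normalized AICc weight.

    AICc is computed from RSS/n (scale-aware Gaussian log-likelihood) with
    parameter count 2; weights ``exp(-delta_AICc / 2)`` are normalized to
    sum to one over the gene's candidates. For very short series where the
    small-sample correction degenerates (n <= 3) plain AIC is used.
    """
    if not fits:
        raise ValueError("need at least one candidate fit")
    n_set = {f.n_obs for f in fits}
    if len(n_set) != 1:
        raise ValueError("candidate fits must share n_obs")
    n = n_set.pop()
    rss = np.array([f.rss for f in fits], dtype=float)
    if not np.all(np.isfinite(rss)):
        raise ValueError("all candidate fits must have finite RSS")
    k = 2
    floor = n * RSS_FLOOR_PER_OBS
    aicc = n * np.log(np.maximum(rss, floor) / n) + 2 * k
    if n > k + 1:
        aicc = aicc + 2 * k * (k + 1) / (n - k - 1)
    w = np.exp(-(aicc - aicc.min()) / 2.0)
    w = w / w.sum()
    return [replace(f, confidence=float(wi)) for f, wi in zip(fits, w)]


def activity_from_expression(
    expr: ExpressionSeries, tf_ids: Sequence[str]
) -> dict[str, np.ndarray]:
    """Proxy TF activity trajectories from the TFs' own expression rows.

    Each TF row present in ``expr`` is min-max scaled to [0, 1]; TFs absent
    from the matrix are omitted (their occupancy falls back to the static
    binding strength).
    """
    out: dict[str, np.ndarray] = {}
    lin = expr.to_linear()
    for tf in tf_ids:
        if tf in lin:
            row = lin.row(tf)
            lo, hi = row.min(), row.max()
            out[tf] = (row - lo) / (hi - lo) if hi > lo else np.ones_like(row)
    return out


def gene_occupancy(
    binding: BindingMatrix,
    gene_id: str,
    n_time: int,
    tf_activity: Mapping[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Per-TF occupancy series for one gene.

    Occupancy is the static binding strength, modulated by the TF's
    activity trajectory when one is supplied:
    ``y_tf(t) = strength(tf, gene) * activity_tf(t)``.
    """
    out = {}
    for tf, s in binding.gene_strengths(gene_id).items():
        if s == 0.0:
            continue
        if tf_activity is not None and tf in tf_activity:
            out[tf] = s * np.asarray(tf_activity[tf], dtype=float)
        else:
            out[tf] = np.full(n_time, s)
    return out


def infer_trn(
    expr: ExpressionSeries,
    binding: BindingMatrix,
    degs: DEGTable,
    conf_min: float = 0.9,
    t_m: int = 1,
    decay: float = 0.0,
    tf_activity: Mapping[str, np.ndarray] | None | str = "from_expression",
    max_pair_order: int = 2,
) -> list[LogicFit]:
    """Infer confident TF logics for every DEG.

    For each DEG the candidate logics over the TFs that bind it are
    enumerated, fitted and scored; fits with confidence >= ``conf_min``
    are returned sorted by (gene, -confidence). Genes without any non-zero
    TF binding are skipped with a log entry. ``tf_activity`` defaults to
    trajectories proxied from the TFs' own expression rows.
    """
    missing = [g for g in degs.gene_ids if g not in expr]
    if missing:
        raise ValueError(f"DEG genes absent from expression matrix: {missing[:5]}")
    if tf_activity == "from_expression":
        tf_activity = activity_from_expression(expr, binding.tf_ids)
    lin = expr.to_linear()
    results: list[LogicFit] = []
    for gene in degs.gene_ids:
        occ = gene_occupancy(binding, gene, lin.n_time_points, tf_activity)
        if not occ:
            logger.info("gene %s has no non-zero TF binding; skipped", gene)
            continue
        fits = [
            fit_logic(lin.row(gene), lin.time_points, logic, occ,
                      gene_id=gene, t_m=t_m, decay=decay)
            for logic in enumerate_logics(list(occ), max_pair_order=max_pair_order)
        ]
        scored = logic_confidence(fits)
        scored.sort(key=lambda f: (-f.confidence, str(f.logic)))
        results.extend(f for f in scored if f.confidence >= conf_min)
    results.sort(key=lambda f: (f.gene_id, -f.confidence, str(f.logic)))
    return results


def fits_to_frame(fits: Sequence[LogicFit]):
    """Tabulate fits as (gene, logic_string, i_max, k_b, rss, confidence)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene": [f.gene_id for f in fits],
            "logic_string": [str(f.logic) for f in fits],
            "i_max": [f.params.i_max for f in fits],
            "k_b": [f.params.k_b for f in fits],
            "rss": [f.rss for f in fits],
            "confidence": [f.confidence for f in fits],
        }
    )
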