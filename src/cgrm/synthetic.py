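"""Synthetic time-series datasets with planted regulatory structure.

The generator emulates the shape of time-course stem-cell-to-cardiomyocyte
differentiation experiments — 10-14 ordered time points, a handful of
master TFs with smooth sigmoidal activity trajectories, thousands of genes
(scaled down for tests), and a small panel of ncRNA regulators — while
providing exact ground truth for closed-loop recovery experiments:

* each gene's expression is integrated forward on the observation grid
  from the saturating kinetic rate law applied to its planted logic's
  combined occupancy (lagged by ``t_m``), so the finite-difference rate
  proxy used in fitting is exact at zero noise;
* ncRNA regulator effects are planted on expression as time-varying
  multiplicative fold-modulations (log-uniform folds in [1.5, 4], up/down
  split evenly), giving the activity-factorization stage genuine signal;
* measurement noise is multiplicative log-normal at a configured CV.

Everything is keyed by a single integer seed and is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    BindingMatrix,
    ExpressionSeries,
    RegulatorTargetMap,
    write_binding,
    write_expression,
    write_regulator_targets,
)
from .logictrn import TFLogic, combine_binding, transcription_rate, KineticParams

#: fold-modulation range for planted ncRNA effects (log-uniform)
NCRNA_FOLD_RANGE = (1.5, 4.0)


def _sigmoids(
    n: int, n_time: int, rng: np.random.Generator, stratified: bool = True
) -> np.ndarray:
    """Smooth logistic trajectories in [0, 1] over an integer time grid.

    Emulates the staggered activation waves and shut-downs of developmental
    regulators: gentle slopes, and (by default) midpoints stratified across
    the first two-thirds of the series with rising/falling directions
    balanced, so that no two regulators share the same switch. With
    ``stratified=False`` midpoints and directions are drawn independently.
    """
    t = np.arange(n_time, dtype=float)
    out = np.empty((n, n_time))
    if stratified and n > 1:
        mids = (np.linspace(0.15, 0.6, n) + rng.uniform(-0.03, 0.03, n)) * (n_time - 1)
        mids = mids[rng.permutation(n)]
        signs = np.resize([1.0, -1.0], n)[rng.permutation(n)]
    else:
        mids = rng.uniform(0.2, 0.8, n) * (n_time - 1)
        signs = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    for i in range(n):
        slope = rng.uniform(0.6, 1.2)
        out[i] = 1.0 / (1.0 + np.exp(-signs[i] * slope * (t - mids[i])))
    return np.clip(out, 0.0, 1.0)


def generate_tf_trajectories(
    n_tfs: int, n_timepoints: int, seed: int = 0
) -> np.ndarray:
    """Per-TF activity/occupancy trajectories in [0, 1] (n_tfs x time)."""
    if n_timepoints < 4:
        raise ValueError("need at least 4 time points")
    rng = np.random.default_rng([seed, 101])
    if n_tfs == 0:
        return np.empty((0, n_timepoints))
    return _sigmoids(n_tfs, n_timepoints, rng)


def _activity_waves(n: int, n_time: int, rng: np.random.Generator) -> np.ndarray:
    """ncRNA regulator activity profiles in [0, 1]: rising waves and pulses.

    Only rising and pulse shapes are used — a decaying effect is expressed
    as a rising activity with negative direction. This avoids a structural
    degeneracy: a falling activity with positive effect equals a rising
    activity with negative effect up to an additive constant, which no
    level-free factorization can tell apart.
    """
    t = np.arange(n_time, dtype=float)
    out = np.empty((n, n_time))
    kinds = np.resize(["rise", "pulse"], n)[rng.permutation(n)]
    mids = (np.linspace(0.15, 0.75, n) + rng.uniform(-0.03, 0.03, n)) * (n_time - 1)
    mids = mids[rng.permutation(n)]
    for i in range(n):
        s = rng.uniform(1.2, 2.2)
        if kinds[i] == "rise":
            out[i] = 1.0 / (1.0 + np.exp(-s * (t - mids[i])))
        else:
            w = rng.uniform(3.5, 5.5)
            a = (1.0 / (1.0 + np.exp(-s * (t - (mids[i] - w / 2))))
                 * 1.0 / (1.0 + np.exp(s * (t - (mids[i] + w / 2)))))
            out[i] = a / a.max()
    return np.clip(out, 0.0, 1.0)


@dataclass
class SyntheticTruth:
    """Complete ground truth of one synthetic dataset."""

    seed: int
    time_points: np.ndarray
    t_m: int
    noise_cv: float
    tf_ids: list[str]
    tf_trajectories: np.ndarray  # n_tfs x time, in [0, 1]
    gene_ids: list[str]
    logics: list[TFLogic]  # planted logic per gene
    i_max: np.ndarray
    k_b: np.ndarray
    e0: np.ndarray
    binding_strengths: np.ndarray  # n_tfs x n_genes, in [0, 1]
    ncrna_ids: list[str] = field(default_factory=list)
    ncrna_classes: list[str] = field(default_factory=list)
    ncrna_activity: np.ndarray | None = None  # n_ncrnas x time, in [0, 1]
    memberships: dict[str, list[str]] = field(default_factory=dict)
    effect_fold: dict[str, dict[str, float]] = field(default_factory=dict)
    effect_dir: dict[str, dict[str, int]] = field(default_factory=dict)

    def tf_activity(self) -> dict[str, np.ndarray]:
        return {tf: self.tf_trajectories[i] for i, tf in enumerate(self.tf_ids)}

    def planted_pairs(self) -> set[tuple[str, str]]:
        """(gene, ncRNA regulator) pairs with a planted effect."""
        return {(g, r) for r, genes in self.memberships.items() for g in genes}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "time_points": self.time_points.tolist(),
            "t_m": self.t_m,
            "noise_cv": self.noise_cv,
            "tf_ids": self.tf_ids,
            "tf_trajectories": self.tf_trajectories.tolist(),
            "gene_ids": self.gene_ids,
            "logics": [str(lg) for lg in self.logics],
            "i_max": self.i_max.tolist(),
            "k_b": self.k_b.tolist(),
            "e0": self.e0.tolist(),
            "binding_strengths": self.binding_strengths.tolist(),
            "ncrna_ids": self.ncrna_ids,
            "ncrna_classes": self.ncrna_classes,
            "ncrna_activity": None if self.ncrna_activity is None
            else self.ncrna_activity.tolist(),
            "memberships": self.memberships,
            "effect_fold": self.effect_fold,
            "effect_dir": self.effect_dir,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            seed=d["seed"],
            time_points=np.asarray(d["time_points"], float),
            t_m=d["t_m"],
            noise_cv=d["noise_cv"],
            tf_ids=d["tf_ids"],
            tf_trajectories=np.asarray(d["tf_trajectories"], float),
            gene_ids=d["gene_ids"],
            logics=[TFLogic.from_string(s) for s in d["logics"]],
            i_max=np.asarray(d["i_max"], float),
            k_b=np.asarray(d["k_b"], float),
            e0=np.asarray(d["e0"], float),
            binding_strengths=np.asarray(d["binding_strengths"], float),
            ncrna_ids=d["ncrna_ids"],
            ncrna_classes=d["ncrna_classes"],
            ncrna_activity=None if d["ncrna_activity"] is None
            else np.asarray(d["ncrna_activity"], float),
            memberships=d["memberships"],
            effect_fold=d["effect_fold"],
            effect_dir={r: {g: int(v) for g, v in m.items()}
                        for r, m in d["effect_dir"].items()},
        )


def make_truth(
    n_genes: int = 100,
    n_tfs: int = 4,
    n_ncrnas: int = 0,
    n_timepoints: int = 11,
    noise_cv: float = 0.0,
    t_m: int = 1,
    seed: int = 17,
    logic_kinds: Sequence[str] = ("AND", "OR", "NOT"),
    decoy_binding: bool = False,
    i_max_range: tuple[float, float] = (1.0, 10.0),
    k_b_range: tuple[float, float] = (0.5, 2.0),
    e0_range: tuple[float, float] = (0.02, 0.1),
    strength_range: tuple[float, float] = (0.5, 0.8),
    membership_mode: str = "disjoint",
) -> SyntheticTruth:
    """Draw a complete planted truth.

    Per gene: a logic drawn uniformly from ``logic_kinds`` over a random TF
    pair (or a single TF for ``'SINGLE'``), kinetic parameters I_max
    log-uniform in [1, 10] expression/time and k_b log-uniform in [0.5, 2],
    and low initial expression uniform in [0.02, 0.1] (targets start near
    off, as induced genes do at the onset of differentiation). Operand TFs
    bind the gene with partial-occupancy strength uniform in [0.5, 0.8];
    with ``decoy_binding`` the remaining TFs also bind, weakly ([0.2,
    0.5]), so logic inference must discriminate among the full candidate
    set. ncRNA memberships partition about 70% of the genes into disjoint
    target blocks by default (``membership_mode='overlapping'`` draws
    independent 10-20% subsets instead); each regulator acts coherently on
    its targets, with the up/down split across regulators.
    """
    rng = np.random.default_rng([seed, 202])
    if n_tfs < 1 or (n_tfs < 2 and any(k != "SINGLE" for k in logic_kinds)):
        raise ValueError("pairwise logics need at least 2 TFs")
    tf_ids = [f"TF{i + 1}" for i in range(n_tfs)]
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    trajectories = generate_tf_trajectories(n_tfs, n_timepoints, seed=seed)

    logics: list[TFLogic] = []
    strengths = np.zeros((n_tfs, n_genes))
    for j in range(n_genes):
        kind = logic_kinds[rng.integers(len(logic_kinds))]
        if kind == "SINGLE":
            ops = rng.choice(n_tfs, size=1, replace=False)
        else:
            ops = rng.choice(n_tfs, size=2, replace=False)
        logics.append(TFLogic(kind, tuple(tf_ids[i] for i in ops)))
        if decoy_binding:
            strengths[:, j] = rng.uniform(0.2, 0.5, size=n_tfs)
        strengths[ops, j] = rng.uniform(*strength_range, size=len(ops))

    i_max = np.exp(rng.uniform(*np.log(i_max_range), size=n_genes))
    k_b = np.exp(rng.uniform(*np.log(k_b_range), size=n_genes))
    e0 = rng.uniform(*e0_range, size=n_genes)

    ncrna_ids, ncrna_classes = [], []
    activity = None
    memberships: dict[str, list[str]] = {}
    effect_fold: dict[str, dict[str, float]] = {}
    effect_dir: dict[str, dict[str, int]] = {}
    if n_ncrnas:
        for i in range(n_ncrnas):
            if i % 2 == 0:
                ncrna_ids.append(f"miR-{i + 1}")
                ncrna_classes.append("miRNA")
            else:
                ncrna_ids.append(f"LNC{i + 1}")
                ncrna_classes.append("lncRNA")
        activity = _activity_waves(n_ncrnas, n_timepoints, rng)
        lo, hi = np.log(NCRNA_FOLD_RANGE[0]), np.log(NCRNA_FOLD_RANGE[1])
        # each regulator acts coherently on its targets (miRNA-like repression
        # or activation); the up/down split is across regulators
        reg_dirs = np.resize([1, -1], n_ncrnas)[rng.permutation(n_ncrnas)]
        if membership_mode == "disjoint":
            block = max(2, int(0.7 * n_genes / n_ncrnas))
            pool = rng.permutation(gene_ids)
            blocks = [sorted(pool[i * block:(i + 1) * block].tolist())
                      for i in range(n_ncrnas)]
        elif membership_mode == "overlapping":
            size_lo = max(2, int(0.10 * n_genes))
            size_hi = max(size_lo + 1, int(0.20 * n_genes))
            blocks = [
                sorted(rng.choice(
                    gene_ids, size=int(rng.integers(size_lo, size_hi + 1)),
                    replace=False).tolist())
                for _ in range(n_ncrnas)
            ]
        else:
            raise ValueError(f"unknown membership mode {membership_mode!r}")
        for i, reg in enumerate(ncrna_ids):
            members = blocks[i]
            memberships[reg] = members
            folds = np.exp(rng.uniform(lo, hi, size=len(members)))
            effect_fold[reg] = {g: float(f) for g, f in zip(members, folds)}
            effect_dir[reg] = {g: int(reg_dirs[i]) for g in members}

    return SyntheticTruth(
        seed=seed,
        time_points=np.arange(n_timepoints, dtype=float),
        t_m=t_m,
        noise_cv=float(noise_cv),
        tf_ids=tf_ids,
        tf_trajectories=trajectories,
        gene_ids=gene_ids,
        logics=logics,
        i_max=i_max,
        k_b=k_b,
        e0=e0,
        binding_strengths=strengths,
        ncrna_ids=ncrna_ids,
        ncrna_classes=ncrna_classes,
        ncrna_activity=activity,
        memberships=memberships,
        effect_fold=effect_fold,
        effect_dir=effect_dir,
    )


def make_ncrna_truth(
    n_genes: int = 300,
    n_tfs: int = 4,
    n_ncrnas: int = 6,
    n_timepoints: int = 14,
    noise_cv: float = 0.05,
    seed: int = 17,
) -> SyntheticTruth:
    """Planted truth for the regulator-target recovery benchmark.

    Same generative model as :func:`make_truth`, but parameterized for
    genes whose dynamics are dominated by post-transcriptional regulation:
    weak transcriptional drive (I_max in [0.1, 0.5]) on an expressed
    baseline (E0 in [2, 6]), so the planted ncRNA fold-modulations are the
    primary temporal signal, and a denser 14-point sampling grid.
    """
    return make_truth(
        n_genes=n_genes, n_tfs=n_tfs, n_ncrnas=n_ncrnas,
        n_timepoints=n_timepoints, noise_cv=noise_cv, seed=seed,
        i_max_range=(0.1, 0.5), e0_range=(2.0, 6.0),
    )


def generate_expression(
    truth: SyntheticTruth, include_tf_rows: bool = False
) -> tuple[ExpressionSeries, BindingMatrix, list[RegulatorTargetMap]]:
    """Integrate the planted model forward into an observable dataset.

    Expression follows ``E(t_k) = E(t_{k-1}) + dt * I_s(t_k)`` with the
    closed-form rate evaluated at the planted logic's combined occupancy
    lagged by ``t_m`` (occupancy before t=0 is held at its t=0 value).
    ncRNA effects multiply member-gene expression by ``fold**(dir * a(t))``
    where ``a`` is the regulator's activity trajectory; log-normal noise at
    the configured CV is applied last. With ``include_tf_rows`` the TFs'
    own expression (an affine image of their activity) is appended, so
    activity can be proxied from the matrix itself.
    """
    n_time = len(truth.time_points)
    dt = np.diff(truth.time_points)
    tf_index = {tf: i for i, tf in enumerate(truth.tf_ids)}
    values = np.empty((len(truth.gene_ids), n_time))
    for j, (gene, logic) in enumerate(zip(truth.gene_ids, truth.logics)):
        ys = []
        for tf in logic.operands:
            i = tf_index[tf]
            ys.append(truth.tf_trajectories[i] * truth.binding_strengths[i, j])
        comb = np.asarray(combine_binding(logic, *ys))
        params = KineticParams(float(truth.i_max[j]), float(truth.k_b[j]), truth.t_m)
        e = np.empty(n_time)
        e[0] = truth.e0[j]
        for k in range(1, n_time):
            lag = max(k - truth.t_m, 0)
            e[k] = e[k - 1] + dt[k - 1] * transcription_rate(params, float(comb[lag]))
        values[j] = e

    for i, reg in enumerate(truth.ncrna_ids):
        a = truth.ncrna_activity[i]
        for gene in truth.memberships.get(reg, []):
            j = truth.gene_ids.index(gene)
            f = truth.effect_fold[reg][gene]
            d = truth.effect_dir[reg][gene]
            values[j] = values[j] * f ** (d * a)

    if truth.noise_cv > 0:
        rng = np.random.default_rng([truth.seed, 303])
        sigma = np.sqrt(np.log1p(truth.noise_cv**2))
        noise = np.exp(rng.normal(-sigma**2 / 2, sigma, size=values.shape))
        values = values * noise

    gene_ids = list(truth.gene_ids)
    if include_tf_rows:
        tf_rows = 1.0 + 9.0 * truth.tf_trajectories
        values = np.vstack([values, tf_rows])
        gene_ids = gene_ids + list(truth.tf_ids)

    expr = ExpressionSeries(gene_ids, truth.time_points.copy(), values)
    binding = BindingMatrix(
        list(truth.tf_ids), list(truth.gene_ids), truth.binding_strengths.copy()
    )
    maps = [
        RegulatorTargetMap(reg, cls, set(truth.memberships[reg]))
        for reg, cls in zip(truth.ncrna_ids, truth.ncrna_classes)
        if truth.memberships.get(reg)
    ]
    return expr, binding, maps


def generate_null_dataset(
    n_genes: int,
    n_samples: int,
    seed: int = 0,
    mean: float = 5.0,
    cv: float = 0.5,
) -> ExpressionSeries:
    """I.i.d. log-normal expression with no regulator structure.

    Every cell is drawn independently with the configured linear-scale mean
    and coefficient of variation; used to calibrate permutation p-values.
    """
    rng = np.random.default_rng([seed, 404])
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(mean) - sigma**2 / 2
    values = rng.lognormal(mu, sigma, size=(n_genes, n_samples))
    gene_ids = [f"N{i + 1:04d}" for i in range(n_genes)]
    return ExpressionSeries(gene_ids, np.arange(n_samples, dtype=float), values)


def write_dataset(
    truth: SyntheticTruth, out_dir: str | Path, include_tf_rows: bool = True
) -> dict[str, Path]:
    """Materialize a truth as the standard input files plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, binding, maps = generate_expression(truth, include_tf_rows=include_tf_rows)
    paths = {
        "expression": out / "expression.tsv",
        "binding": out / "binding.tsv",
        "regulator_targets": out / "regulator_targets.tsv",
        "truth": out / "truth.json",
    }
    write_expression(expr, paths["expression"])
    write_binding(binding, paths["binding"])
    write_regulator_targets(maps, paths["regulator_targets"])
    truth.to_json(paths["truth"])
    return paths
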