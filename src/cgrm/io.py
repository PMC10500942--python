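"""Readers, writers and core domain containers.

All downstream modules operate on the validated containers defined here:
:class:`ExpressionSeries` (genes x ordered time points),
:class:`BindingMatrix` (TF x gene binding strengths, normalized to [0, 1]),
:class:`RegulatorTargetMap` (one regulator's known target set) and
:class:`GeneSetCollection` (named gene sets over a universe, GMT-backed).

Parsers reject malformed input instead of coercing it: duplicate gene
identifiers, non-monotone time headers and non-numeric cells are hard
errors that name the offending row/column.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

REGULATOR_CLASSES = ("TF", "miRNA", "lncRNA")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionSeries:
    """Gene expression over ordered time points.

    Parameters
    ----------
    gene_ids
        Unique, ordered gene identifiers (opaque, case-sensitive strings).
    time_points
        Strictly increasing sampling times (hours or days; unit recorded
        in ``metadata['time_unit']`` when known).
    values
        ``(n_genes, n_time_points)`` matrix. Non-negative when
        ``scale == 'linear'``; negatives permitted for ``'log2'``.
    scale
        ``'linear'`` or ``'log2'``.
    """

    gene_ids: list[str]
    time_points: np.ndarray
    values: np.ndarray
    scale: str = "linear"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.time_points = np.asarray(self.time_points, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))
            raise FormatError(f"duplicate gene id {dup!r}")
        if self.time_points.ndim != 1 or np.any(np.diff(self.time_points) <= 0):
            raise FormatError(
                f"time points must be strictly increasing, got {self.time_points.tolist()}"
            )
        if self.values.shape != (len(self.gene_ids), len(self.time_points)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.time_points)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression matrix contains non-finite values")
        if self.scale == "linear" and np.any(self.values < 0):
            raise FormatError("linear-scale expression must be non-negative")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_time_points(self) -> int:
        return len(self.time_points)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self._index[gene_id]]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionSeries":
        idx = [self._index[g] for g in gene_ids]
        return ExpressionSeries(
            list(gene_ids), self.time_points.copy(), self.values[idx].copy(),
            scale=self.scale, metadata=dict(self.metadata),
        )

    def to_linear(self) -> "ExpressionSeries":
        """Return a linear-scale copy (2**x applied when stored as log2)."""
        if self.scale == "linear":
            return self
        return ExpressionSeries(
            list(self.gene_ids), self.time_points.copy(),
            np.exp2(self.values), scale="linear", metadata=dict(self.metadata),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.time_points)


@dataclass
class BindingMatrix:
    """TF x gene binding strengths on a common [0, 1] scale.

    Missing (TF, gene) pairs are zero. Strengths loaded from raw
    binding-evidence tables (peak scores, enrichment scores) are min-max
    normalized per TF so that heterogeneous evidence types share one
    bounded scale, which the logic-combination algebra requires.
    """

    tf_ids: list[str]
    gene_ids: list[str]
    strengths: np.ndarray

    def __post_init__(self) -> None:
        self.tf_ids = [str(t) for t in self.tf_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.strengths = np.asarray(self.strengths, dtype=float)
        if self.strengths.shape != (len(self.tf_ids), len(self.gene_ids)):
            raise ValueError("strengths shape does not match id lists")
        if np.any(self.strengths < 0) or np.any(self.strengths > 1):
            raise ValueError("binding strengths must lie in [0, 1]")
        self._tf_index = {t: i for i, t in enumerate(self.tf_ids)}
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    def strength(self, tf_id: str, gene_id: str) -> float:
        i = self._tf_index.get(tf_id)
        j = self._gene_index.get(gene_id)
        if i is None or j is None:
            return 0.0
        return float(self.strengths[i, j])

    def gene_strengths(self, gene_id: str) -> dict[str, float]:
        """Strengths of every TF for one gene (absent gene -> all zeros)."""
        j = self._gene_index.get(gene_id)
        if j is None:
            return {t: 0.0 for t in self.tf_ids}
        return {t: float(self.strengths[i, j]) for i, t in enumerate(self.tf_ids)}


@dataclass
class RegulatorTargetMap:
    regulator_id: str
    regulator_class: str
    target_gene_ids: set[str]

    def __post_init__(self) -> None:
        if self.regulator_class not in REGULATOR_CLASSES:
            raise FormatError(
                f"unknown regulator class {self.regulator_class!r} for "
                f"{self.regulator_id!r}; expected one of {REGULATOR_CLASSES}"
            )
        self.target_gene_ids = set(self.target_gene_ids)
        if not self.target_gene_ids:
            raise ValueError(f"regulator {self.regulator_id!r} has an empty target set")


@dataclass
class GeneSetCollection:
    """Named gene sets with an enclosing universe."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        members = set().union(*self.sets.values()) if self.sets else set()
        if self.universe is None:
            self.universe = members
        else:
            self.universe = set(self.universe)
            missing = members - self.universe
            if missing:
                raise ValueError(
                    f"{len(missing)} set members outside the universe, e.g. "
                    f"{sorted(missing)[:3]}"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, header=0, dtype=str)


def read_expression(path: str | Path, scale: str = "linear") -> ExpressionSeries:
    """Read a genes-in-rows TSV/CSV whose header row holds numeric time points."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a gene-id column plus >=1 time column")
    gene_ids = df.iloc[:, 0].astype(str).tolist()
    dup = pd.Series(gene_ids)[pd.Series(gene_ids).duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate gene id {dup.iloc[0]!r}")
    try:
        times = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric time header: {exc}") from exc
    if np.any(np.diff(times) <= 0):
        raise FormatError(f"{path}: time header not strictly increasing: {times.tolist()}")
    values = np.empty((len(gene_ids), len(times)))
    for j, col in enumerate(df.columns[1:]):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(float)
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].iloc[0, 0]
            raise FormatError(
                f"{path}: non-numeric expression value at gene {bad!r}, time column {col!r}"
            ) from None
    return ExpressionSeries(gene_ids, times, values, scale=scale)


def write_expression(expr: ExpressionSeries, path: str | Path) -> None:
    df = expr.to_frame()
    df.columns = [format(t, "g") for t in expr.time_points]
    df.index.name = "gene"
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    df.to_csv(path, sep=sep)


def read_binding(path: str | Path, normalize: bool | str = "auto") -> BindingMatrix:
    """Read a long-format (tf, gene, strength) table into a BindingMatrix.

    Raw binding evidence (peak heights, enrichment scores) arrives on
    arbitrary scales, so strengths are min-max scaled per TF onto (0, 1]
    (absent pairs stay 0; a small floor keeps the weakest observed pair
    distinguishable from absence). ``normalize='auto'`` (default) skips
    rescaling when every value is already in [0, 1]; ``True`` forces it,
    ``False`` rejects out-of-range input instead.
    """
    df = _read_table(path)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected columns (tf, gene, strength)")
    tf_col, gene_col, s_col = df.columns[:3]
    try:
        raw = pd.to_numeric(df[s_col], errors="raise").to_numpy(float)
    except (ValueError, TypeError):
        raise FormatError(f"{path}: non-numeric binding strength") from None
    tfs = sorted(df[tf_col].astype(str).unique())
    genes = sorted(df[gene_col].astype(str).unique())
    ti = {t: i for i, t in enumerate(tfs)}
    gi = {g: i for i, g in enumerate(genes)}
    mat = np.zeros((len(tfs), len(genes)))
    for tf, gene, s in zip(df[tf_col].astype(str), df[gene_col].astype(str), raw):
        mat[ti[tf], gi[gene]] = s
    if normalize == "auto":
        normalize = bool(np.any(mat < 0) or np.any(mat > 1))
    if normalize:
        for i in range(len(tfs)):
            row = mat[i]
            nz = row != 0
            if not nz.any():
                continue
            lo, hi = row[nz].min(), row[nz].max()
            if hi == lo:
                mat[i, nz] = 1.0
            else:
                # map the occupied entries onto (0, 1], keeping absent pairs at 0
                mat[i, nz] = 0.05 + 0.95 * (row[nz] - lo) / (hi - lo)
    elif np.any(mat < 0) or np.any(mat > 1):
        raise FormatError(f"{path}: strengths outside [0,1] with normalize=False")
    return BindingMatrix(tfs, genes, mat)


def write_binding(binding: BindingMatrix, path: str | Path) -> None:
    rows = []
    for i, tf in enumerate(binding.tf_ids):
        for j, gene in enumerate(binding.gene_ids):
            s = binding.strengths[i, j]
            if s != 0:
                rows.append((tf, gene, s))
    pd.DataFrame(rows, columns=["tf", "gene", "strength"]).to_csv(
        path, sep="\t", index=False
    )


def read_regulator_targets(path: str | Path) -> list[RegulatorTargetMap]:
    """Read a (regulator, class, target) TSV into one map per regulator."""
    df = _read_table(path)
    if df.empty:
        return []
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected columns (regulator, class, target)")
    reg_col, cls_col, tgt_col = df.columns[:3]
    maps: dict[str, RegulatorTargetMap] = {}
    for reg, cls, tgt in zip(
        df[reg_col].astype(str), df[cls_col].astype(str), df[tgt_col].astype(str)
    ):
        if cls not in REGULATOR_CLASSES:
            raise FormatError(
                f"{path}: unknown regulator class {cls!r} for {reg!r}"
            )
        if reg in maps:
            if maps[reg].regulator_class != cls:
                raise FormatError(f"{path}: regulator {reg!r} listed with two classes")
            maps[reg].target_gene_ids.add(tgt)
        else:
            maps[reg] = RegulatorTargetMap(reg, cls, {tgt})
    return [maps[r] for r in sorted(maps)]


def write_regulator_targets(maps: Iterable[RegulatorTargetMap], path: str | Path) -> None:
    rows = [
        (m.regulator_id, m.regulator_class, t)
        for m in maps
        for t in sorted(m.target_gene_ids)
    ]
    pd.DataFrame(rows, columns=["regulator", "class", "target"]).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated members)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(parts)} fields, need >=3"
                )
            name, desc, members = parts[0], parts[1], parts[2:]
            sets[name] = {m for m in members if m}
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions, universe=universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(collection[name])]) + "\n")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the published operating point."""

    expression: str = ""
    binding: str = ""
    regulator_targets: str = ""
    gene_sets: str = ""
    expression_scale: str = "linear"
    group_a: list[int] = field(default_factory=lambda: [0, 1, 2])
    group_b: list[int] = field(default_factory=lambda: [-3, -2, -1])
    fc_min: float = 2.0
    p_max: float = 0.05
    adjust_p: bool = False
    conf_min: float = 0.9
    t_m: int = 1
    decay: float = 0.0
    n_perm: int = 1000
    alpha: float = 0.05
    z_method: str = "median"
    z_from_degs: bool = False
    perm_scheme: str = "within_gene"
    gap: float = 0.05
    seed: int = 17
    out_dir: str = "cgrm_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for key, value in raw.items():
            if isinstance(value, Mapping):
                flat.update(value)
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**flat)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
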