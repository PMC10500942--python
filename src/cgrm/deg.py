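"""Differential expression between two time-point groups.

The framework's contribution is the downstream use of DEGs, not the DE
engine itself, so the built-in test is deliberately simple: Welch's t on
log2 values with a pseudocount, plus the published cutoffs (fold change
>= 2.0, p < 0.05). Externally computed DEG tables (edgeR/limma output)
can be loaded with :func:`read_deg_table` instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionSeries

PSEUDOCOUNT = 1.0


@dataclass
class DEGTable:
    """Per-gene log2 fold change, p-value and direction.

    ``direction`` is ``'up'`` iff ``log2_fold_change > 0``; a fold change of
    exactly 0 is labelled ``'up'`` by convention (it never survives any
    fc_min > 1 filter).
    """

    frame: pd.DataFrame  # columns: gene_id, log2_fold_change, p_value, direction

    COLUMNS = ("gene_id", "log2_fold_change", "p_value", "direction")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"DEG table missing columns {sorted(missing)}")
        f = self.frame
        if len(f):
            if ((f["p_value"] <= 0) | (f["p_value"] > 1)).any():
                raise ValueError("p values must lie in (0, 1]")
            expect = np.where(f["log2_fold_change"].to_numpy() > 0, "up",
                              np.where(f["log2_fold_change"].to_numpy() < 0, "down", "up"))
            if (f["direction"].to_numpy() != expect).any():
                raise ValueError("direction inconsistent with log2 fold change sign")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def gene_ids(self) -> list[str]:
        return self.frame["gene_id"].tolist()

    def genes(self, direction: str | None = None) -> list[str]:
        if direction is None:
            return self.gene_ids
        sub = self.frame[self.frame["direction"] == direction]
        return sub["gene_id"].tolist()

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def read_deg_table(path: str | Path) -> DEGTable:
    """Load a DEG table (own output or external edgeR/limma-style TSV)."""
    df = pd.read_csv(path, sep="\t")
    rename = {"logFC": "log2_fold_change", "PValue": "p_value", "P.Value": "p_value",
              "gene": "gene_id"}
    df = df.rename(columns=rename)
    if "direction" not in df.columns and "log2_fold_change" in df.columns:
        df["direction"] = np.where(df["log2_fold_change"] > 0, "up",
                                   np.where(df["log2_fold_change"] < 0, "down", "up"))
    df["gene_id"] = df["gene_id"].astype(str)
    return DEGTable(df[list(DEGTable.COLUMNS)])


def _direction(log2_fc: np.ndarray) -> np.ndarray:
    return np.where(log2_fc < 0, "down", "up")


def compute_de(
    expr: ExpressionSeries,
    group_a: Sequence[int],
    group_b: Sequence[int],
    adjust: bool = False,
) -> DEGTable:
    """Welch's t-test between two disjoint groups of time-point columns.

    Fold changes are ``log2(mean_b / mean_a)`` on the linear scale (with a
    pseudocount of 1 guarding zeros); the test runs on log2 values. Groups
    of size 1 yield p = 1 with a warning, fold changes still reported.
    With ``adjust=True`` p-values are Benjamini-Hochberg corrected before
    any downstream cutoff.
    """
    ga = [int(i) % expr.n_time_points for i in group_a]
    gb = [int(i) % expr.n_time_points for i in group_b]
    if not ga or not gb:
        raise ValueError("both groups must be non-empty")
    if set(ga) & set(gb):
        raise ValueError(f"groups overlap at time-point indices {sorted(set(ga) & set(gb))}")
    lin = expr.to_linear().values
    log2v = np.log2(lin + PSEUDOCOUNT)
    a, b = log2v[:, ga], log2v[:, gb]
    mean_a = lin[:, ga].mean(axis=1) + PSEUDOCOUNT
    mean_b = lin[:, gb].mean(axis=1) + PSEUDOCOUNT
    log2_fc = np.log2(mean_b / mean_a)
    if len(ga) < 2 or len(gb) < 2:
        warnings.warn("a group has size 1; p-values set to 1", stacklevel=2)
        p = np.ones(expr.n_genes)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
        # zero within-group variance in both groups: identical values, no evidence
        p = np.where(np.isfinite(p), p, 1.0)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    if adjust:
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, method="fdr_bh")[1]
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    frame = pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "log2_fold_change": log2_fc,
            "p_value": p,
            "direction": _direction(log2_fc),
        }
    )
    return DEGTable(frame)


def filter_degs(table: DEGTable, fc_min: float = 2.0, p_max: float = 0.05) -> DEGTable:
    """Keep genes with ``|log2FC| >= log2(fc_min)`` and ``p < p_max``."""
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1")
    f = table.frame
    keep = (f["log2_fold_change"].abs() >= np.log2(fc_min)) & (f["p_value"] < p_max)
    return DEGTable(f[keep].reset_index(drop=True))
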