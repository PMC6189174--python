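"""Tenth-centile marker binarization, co-expression tables and subset rules.

A cell is called positive for a marker when its expression is at or above a
threshold set at the tenth centile of expression among cells in which at
least one transcript of that gene was detected — i.e. the threshold includes
the 90% of expressing cells with the highest expression (ties at the
threshold are included on the positive side). Because the rule is rank-based,
any monotone rescaling of expression (counts, TPM, log) yields the same
calls.

Thresholds are always computed per gene over the full matrix, then applied
to any cell subset, so co-expression percentages and selection rules across
tissues share one threshold per gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .matrix_io import CountMatrix


@dataclass
class BinaryCall:
    """Positivity calls for one gene under the tenth-centile rule."""

    gene_id: str
    threshold_value: float
    positive: pd.Series  # boolean per cell
    n_expressing: int


@dataclass
class SelectionRule:
    """Tissue-scoped marker requirement: every listed gene must match its flag."""

    tissue: str
    requirements: list[tuple[str, bool]]  # (gene, require_positive)


def positivity_threshold(expr_vector: pd.Series, counts_vector: pd.Series, gene_id: str = "") -> BinaryCall:
    """Tenth-centile positivity call for one gene.

    Expressing cells are those with at least one transcript. The threshold is
    placed so that, with all-distinct expression values, exactly
    ``ceil(0.9 * n_expressing)`` cells are at or above it; ties at the
    threshold are all called positive. No expressing cells is not an error —
    it yields zero positives.
    """
    if not expr_vector.index.equals(counts_vector.index):
        raise ValueError("expression and count vectors cover different cells")
    expressing = counts_vector >= 1
    n_expr = int(expressing.sum())
    if n_expr == 0:
        return BinaryCall(
            gene_id=gene_id,
            threshold_value=np.nan,
            positive=pd.Series(False, index=expr_vector.index),
            n_expressing=0,
        )
    values = np.sort(expr_vector[expressing].to_numpy(dtype=float))
    n_keep = int(np.ceil(0.9 * n_expr))
    threshold = float(values[n_expr - n_keep])
    positive = expressing & (expr_vector >= threshold)
    return BinaryCall(
        gene_id=gene_id,
        threshold_value=threshold,
        positive=positive,
        n_expressing=n_expr,
    )


def _calls_for_genes(matrix: CountMatrix, genes: list[str]) -> dict[str, BinaryCall]:
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise ValueError(f"genes not in matrix: {missing}")
    counts = matrix.values
    return {
        g: positivity_threshold(counts.loc[g].astype(float), counts.loc[g], gene_id=g)
        for g in genes
    }


def combination_table(genes: list[str], matrix: CountMatrix, subset=None) -> pd.DataFrame:
    """Percentage of subset cells in each positive/negative marker combination.

    Thresholds are computed on the full matrix; percentages are over the
    ``subset`` cells (default all cells) and sum to 100 across the
    2^len(genes) combinations, including all-negative.
    """
    if not 1 <= len(genes) <= 5:
        raise ValueError("combination_table supports 1–5 genes")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes in combination request")
    cells = list(matrix.values.columns) if subset is None else list(subset)
    if not cells:
        raise ValueError("empty cell subset")
    missing = [c for c in cells if c not in matrix.values.columns]
    if missing:
        raise ValueError(f"subset cells not in matrix: {missing[:5]}")
    calls = _calls_for_genes(matrix, genes)
    flags = pd.DataFrame({g: calls[g].positive.loc[cells] for g in genes})
    rows = []
    for combo in product([True, False], repeat=len(genes)):
        mask = np.ones(len(cells), dtype=bool)
        for g, flag in zip(genes, combo):
            mask &= flags[g].to_numpy() == flag
        label = "/".join(f"{g}{'+' if flag else '-'}" for g, flag in zip(genes, combo))
        rows.append(
            {
                "combination": label,
                "n_cells": int(mask.sum()),
                "percent": 100.0 * mask.sum() / len(cells),
            }
        )
    return pd.DataFrame(rows).set_index("combination")


def select_cells(matrix: CountMatrix, rules: list[SelectionRule]) -> list[str]:
    """Cells retained under the tissue-scoped marker rules.

    A cell is retained iff every rule for its tissue holds; cells of tissues
    with no rule are retained unconditionally. Thresholds come from the full
    matrix.
    """
    tissues = set(matrix.cell_table["tissue"])
    genes = sorted({g for r in rules for g, _ in r.requirements})
    for rule in rules:
        if rule.tissue not in tissues:
            raise ValueError(f"unknown tissue {rule.tissue!r}")
    calls = _calls_for_genes(matrix, genes)
    keep = []
    for cell in matrix.values.columns:
        tissue = matrix.cell_table.loc[cell, "tissue"]
        ok = True
        for rule in rules:
            if rule.tissue != tissue:
                continue
            for gene, require_positive in rule.requirements:
                if bool(calls[gene].positive.loc[cell]) != require_positive:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            keep.append(cell)
    return keep
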