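"""Control-anchored cell QC, TMM normalization, FPKM/TPM conversion, gene filters.

The QC threshold is anchored on the plate's control wells: it is set one
count above the largest negative-control total (fragments mapping to
biological genes), must retain every positive control, and every retained
cell is a sample well at or above it. Normalization follows the
trimmed-mean-of-M-values (TMM) scheme: a reference cell is picked by
upper-quartile count fraction, per-cell log-ratios (M) and log-abundances (A)
against the reference are doubly trimmed (30% each side on M, 5% each side on
A), and the scaling factor is two to the precision-weighted mean of the
retained M values, rescaled so factors have geometric mean one.

Spike-ins are excluded from TMM, from both gene filters, and from all
downstream clustering and differential expression; they inform the technical
noise model only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import nearest_rank_quantile
from .errors import (
    ConfigurationError,
    DegenerateCellError,
    EmptyResultError,
    QCConflictError,
    UnitError,
)
from .matrix_io import CountMatrix, ExpressionMatrix


@dataclass
class QCThreshold:
    """Per-plate QC threshold with the totals and exclusions behind it."""

    threshold: int
    per_well_totals: pd.Series
    excluded_cells: list[str]


@dataclass
class NormFactors:
    """TMM scaling factors (geometric mean 1) and library sizes per cell."""

    tmm_factor: pd.Series
    library_size: pd.Series

    def __post_init__(self):
        f = self.tmm_factor.to_numpy(dtype=float)
        if not np.all(np.isfinite(f)) or (f <= 0).any():
            raise ValueError("TMM factors must be finite and positive")
        if abs(np.exp(np.mean(np.log(f))) - 1.0) > 1e-9:
            raise ValueError("TMM factors must have geometric mean 1")

    @property
    def effective_size(self) -> pd.Series:
        return self.library_size * self.tmm_factor


def qc_threshold(
    matrix: CountMatrix,
    override: int | None = None,
    *,
    mad_k: float | None = None,
) -> QCThreshold:
    """Control-anchored QC threshold on per-well biological-gene totals.

    The threshold is (max negative-control total) + 1, or ``override`` when
    given (in which case control-consistency checks are skipped). A positive
    control below the computed threshold raises :class:`QCConflictError`.
    ``mad_k`` optionally adds an outlier rule on log10 totals of sample wells
    (exclude wells outside median ± mad_k·MAD); off by default.
    """
    totals = matrix.nonspike_totals()
    well_type = matrix.well_type
    neg = totals[well_type == "neg_control"]
    pos = totals[well_type == "pos_control"]

    if override is not None:
        threshold = int(override)
    else:
        if neg.empty or pos.empty:
            raise ConfigurationError(
                "need at least one negative and one positive control well, or an override"
            )
        threshold = int(neg.max()) + 1
        below = pos[pos < threshold]
        if not below.empty:
            raise QCConflictError(
                f"positive control(s) below threshold {threshold}: "
                f"{dict(below.astype(int))}"
            )

    sample = totals[well_type == "sample"]
    excluded = set(sample[sample < threshold].index)
    if mad_k is not None and len(sample) > 0:
        logt = np.log10(sample.to_numpy(dtype=float) + 1.0)
        med = np.median(logt)
        mad = np.median(np.abs(logt - med))
        if mad > 0:
            out = np.abs(logt - med) > mad_k * mad
            excluded |= set(sample.index[out])
    return QCThreshold(
        threshold=threshold,
        per_well_totals=totals,
        excluded_cells=sorted(excluded),
    )


def filter_cells(matrix: CountMatrix, qc: QCThreshold) -> CountMatrix:
    """Retain sample wells at/above the threshold; drop all control wells."""
    well_type = matrix.well_type
    keep = [
        c
        for c in matrix.values.columns
        if well_type[c] == "sample"
        and qc.per_well_totals[c] >= qc.threshold
        and c not in qc.excluded_cells
    ]
    if not keep:
        raise EmptyResultError("no cells survive QC filtering")
    return matrix.subset_cells(keep)


# -- TMM ------------------------------------------------------------------


def _choose_reference(counts: np.ndarray) -> int:
    """Cell whose upper-quartile count fraction is closest to the across-cell mean."""
    lib = counts.sum(axis=0).astype(float)
    uq = np.array(
        [nearest_rank_quantile(counts[:, j], 0.75) / lib[j] for j in range(counts.shape[1])]
    )
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_one(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    *,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> float:
    """edgeR-style TMM log2 factor of one cell against the reference."""
    shared = (obs > 0) & (ref > 0)
    if not shared.any():
        raise DegenerateCellError("cell shares no positive genes with the reference")
    o = obs[shared].astype(float)
    r = ref[shared].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # delta-method (binomial) precision weights for the log ratio
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    n = m.size
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    # rank-based double trim; average ranks keep ties deterministic
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        keep = np.ones(n, dtype=bool)  # tiny panels: fall back to no trim
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def tmm_factors(matrix: CountMatrix) -> NormFactors:
    """TMM scaling factors over biological genes, rescaled to geometric mean 1."""
    if matrix.n_cells < 2:
        raise ValueError("TMM needs at least 2 cells")
    counts = matrix.values.loc[~matrix.spike_mask.to_numpy()].to_numpy()
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = matrix.values.columns[lib <= 0].tolist()
        raise DegenerateCellError(f"cells with zero biological counts: {bad[:5]}")
    ref_idx = _choose_reference(counts)
    ref = counts[:, ref_idx]
    log_factors = np.array(
        [
            0.0
            if j == ref_idx
            else _tmm_one(counts[:, j], ref, lib[j], lib[ref_idx])
            for j in range(counts.shape[1])
        ]
    )
    log_factors -= log_factors.mean()  # geometric mean 1
    factors = pd.Series(2.0**log_factors, index=matrix.values.columns, name="tmm_factor")
    library = pd.Series(lib.astype(np.int64), index=matrix.values.columns, name="library_size")
    return NormFactors(tmm_factor=factors, library_size=library)


# -- expression units -----------------------------------------------------


def fpkm(matrix: CountMatrix, lengths: dict[str, int], norm: NormFactors) -> ExpressionMatrix:
    """FPKM over biological genes: count × 1e9 / (length_bp × effective library size)."""
    bio = matrix.values.loc[~matrix.spike_mask.to_numpy()]
    missing = [g for g in bio.index if g not in lengths or not np.isfinite(lengths[g])]
    if missing:
        raise ValueError(f"genes missing a length for FPKM: {missing[:10]}")
    length = np.array([lengths[g] for g in bio.index], dtype=float)
    eff = norm.effective_size.loc[bio.columns].to_numpy(dtype=float)
    values = bio.to_numpy(dtype=float) * 1e9 / (length[:, None] * eff[None, :])
    return ExpressionMatrix(pd.DataFrame(values, index=bio.index, columns=bio.columns), "FPKM")


def filter_genes_fpkm(
    expr: ExpressionMatrix, min_fpkm: float = 4.0, min_cells: int = 3
) -> pd.Series:
    """Keep genes with FPKM >= min_fpkm in >= min_cells cells."""
    if expr.unit != "FPKM":
        raise UnitError(f"expected FPKM, got {expr.unit}")
    qualifying = (expr.values >= min_fpkm).sum(axis=1)
    return qualifying >= min_cells


def tpm(matrix: CountMatrix, lengths: dict[str, int], genes=None) -> ExpressionMatrix:
    """Length-normalized TPM over the given biological gene set (re-normalised).

    Restricting ``genes`` to the FPKM-filtered set implements the conversion
    after re-normalisation on the retained genes; each cell's TPM column sums
    to 1e6.
    """
    bio = matrix.values.loc[~matrix.spike_mask.to_numpy()]
    if genes is not None:
        bio = bio.loc[list(genes)]
    missing = [g for g in bio.index if g not in lengths or not np.isfinite(lengths[g])]
    if missing:
        raise ValueError(f"genes missing a length for TPM: {missing[:10]}")
    length_kb = np.array([lengths[g] for g in bio.index], dtype=float) / 1e3
    rate = bio.to_numpy(dtype=float) / length_kb[:, None]
    totals = rate.sum(axis=0)
    if (totals <= 0).any():
        bad = bio.columns[totals <= 0].tolist()
        raise ValueError(f"cells with zero total over the gene set: {bad[:5]}")
    values = rate / totals[None, :] * 1e6
    return ExpressionMatrix(pd.DataFrame(values, index=bio.index, columns=bio.columns), "TPM")


def filter_low_variability(expr: ExpressionMatrix) -> pd.Series:
    """Drop genes in the top decile of mean expression AND below the fifth
    centile of coefficient of variation (both nearest-rank, over the genes of
    ``expr``); keep everything else."""
    if expr.unit != "TPM":
        raise UnitError(f"expected TPM, got {expr.unit}")
    if expr.values.shape[0] < 20:
        raise ValueError("need at least 20 genes for the variability filter")
    means = expr.values.mean(axis=1)
    sds = expr.values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = (sds / means).fillna(np.inf)
    mean_cut = nearest_rank_quantile(means, 0.90)
    cv_cut = nearest_rank_quantile(cv.replace(np.inf, np.nan).dropna(), 0.05)
    drop = (means >= mean_cut) & (cv < cv_cut)
    return ~drop


def log2_tpm(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) transform used for clustering geometry."""
    if expr.unit != "TPM":
        raise UnitError(f"expected TPM, got {expr.unit}")
    return ExpressionMatrix(np.log2(expr.values + 1.0), "log2TPM")
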