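"""Synthetic single-cell plates with spike-ins and control wells.

The generator emulates the statistical structure the downstream analysis
assumes: discrete cell populations distinguished by marker genes, log-normal
per-cell sequencing depth, negative-binomial overdispersion, mean-dependent
dropout, spike-in transcripts present at a constant expected level in every
well (mimicking an ERCC mix added at a fixed dilution), and negative/positive
control wells (blank wells, three of which receive a small bulk-RNA aliquot,
mirroring plate designs used for plate-based scRNA-seq QC).

Counts for gene g in cell c are drawn as

    x_gc ~ NB(mean = lambda_gc, var = lambda_gc + phi * lambda_gc^2)
    lambda_gc = base_g * multiplier(g, group(c)) * s_c          (biological genes)
    lambda_gc = spike_level_g                                   (spike-ins; s_c not applied)

followed by Bernoulli thinning to zero with probability
1 - p_detect(lambda_gc), where p_detect is a logistic curve in
log2(lambda + 1) with midpoint ``dropout_midpoint`` and slope
``dropout_slope``. Size factors s_c are log-normal(0, size_factor_sd) and are
not applied to spike-ins, which enter wells at a fixed dilution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._utils import rng_for
from .matrix_io import CountMatrix


@dataclass
class GenePanel:
    """Gene annotation panel: biological genes plus a spike-in dilution series."""

    gene_id: list[str]
    length_bp: np.ndarray  # per gene, >= 100 for biological genes
    base_mean: np.ndarray  # expected transcript abundance (NaN for spike-ins)
    is_spikein: np.ndarray
    spike_level: np.ndarray  # expected count per well (NaN for biological genes)

    def __post_init__(self):
        if len(set(self.gene_id)) != len(self.gene_id):
            raise ValueError("gene ids must be unique")
        spikes = np.asarray(self.is_spikein, dtype=bool)
        if np.isnan(np.asarray(self.spike_level, dtype=float)[spikes]).any():
            raise ValueError("every spike-in needs a spike_level")
        bio = ~spikes
        if np.isnan(np.asarray(self.base_mean, dtype=float)[bio]).any():
            raise ValueError("every biological gene needs a base_mean")
        if (np.asarray(self.length_bp, dtype=float)[bio] < 100).any():
            raise ValueError("biological gene lengths must be >= 100 bp")

    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "length_bp": np.asarray(self.length_bp, dtype=np.int64),
                "is_spikein": np.asarray(self.is_spikein, dtype=bool),
            },
            index=pd.Index(self.gene_id, name="gene_id"),
        )


@dataclass
class GroupDesign:
    name: str
    n_cells: int
    marker_gene_ids: list[str] = field(default_factory=list)
    marker_multiplier: float = 1.0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError(f"group {self.name}: n_cells must be >= 1")
        if self.marker_multiplier < 1:
            raise ValueError(f"group {self.name}: marker_multiplier must be >= 1")


@dataclass
class CellDesign:
    """Population layout of a plate: groups of cells and their marker genes."""

    groups: list[GroupDesign]
    size_factor_sd: float = 0.25

    def __post_init__(self):
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        if self.size_factor_sd < 0:
            raise ValueError("size_factor_sd must be non-negative")


@dataclass
class NoiseParams:
    """Generative technical-noise parameters.

    ``dispersion`` is the NB overdispersion phi (var = mu + phi mu^2);
    ``dropout_midpoint`` is the log2 mean at 50% detection (-inf disables
    dropout); ``dropout_slope`` > 0 makes detection non-decreasing in the mean.
    """

    dispersion: float = 0.5
    dropout_midpoint: float = 1.0
    dropout_slope: float = 1.5

    def __post_init__(self):
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.dropout_slope <= 0:
            raise ValueError("dropout_slope must be positive")

    def p_detect(self, mean: np.ndarray) -> np.ndarray:
        if np.isneginf(self.dropout_midpoint):
            return np.ones_like(np.asarray(mean, dtype=float))
        x = np.log2(np.asarray(mean, dtype=float) + 1.0)
        return expit(self.dropout_slope * (x - self.dropout_midpoint))


def build_panel(
    n_genes: int,
    n_spikeins: int,
    seed: int,
    *,
    log_mean_location: float = np.log(30.0),
    log_mean_sd: float = 1.0,
    top_spike_level: float = 512.0,
) -> GenePanel:
    """Panel of ``n_genes`` biological genes plus ``n_spikeins`` spike-ins.

    Base means are log-normal(log_mean_location, log_mean_sd); spike levels
    form a two-fold dilution series from ``top_spike_level`` downward, so a
    panel with n spike-ins spans a 2^(n-1) dynamic range (>= 2^10 at the
    default 12 spike-ins).
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if n_spikeins < 4:
        raise ValueError("n_spikeins must be >= 4")
    rng = rng_for(seed, "panel")
    gene_ids = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    spike_ids = [f"ERCC-{i + 1:05d}" for i in range(n_spikeins)]
    base = rng.lognormal(mean=log_mean_location, sigma=log_mean_sd, size=n_genes)
    lengths = rng.integers(200, 5001, size=n_genes)
    spike_lengths = rng.integers(250, 2001, size=n_spikeins)
    levels = top_spike_level / (2.0 ** np.arange(n_spikeins))
    return GenePanel(
        gene_id=gene_ids + spike_ids,
        length_bp=np.concatenate([lengths, spike_lengths]),
        base_mean=np.concatenate([base, np.full(n_spikeins, np.nan)]),
        is_spikein=np.concatenate(
            [np.zeros(n_genes, dtype=bool), np.ones(n_spikeins, dtype=bool)]
        ),
        spike_level=np.concatenate([np.full(n_genes, np.nan), levels]),
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, var = mean + phi mean^2); Poisson in the phi → 0 limit."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    size_param = 1.0 / phi
    p = size_param / (size_param + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    positive = mean > 0
    out[positive] = rng.negative_binomial(size_param, p[positive])
    return out


def simulate_counts(
    panel: GenePanel, design: CellDesign, noise: NoiseParams, seed: int
) -> CountMatrix:
    """Draw one plate of counts for the panel under the given design and noise."""
    spikes = np.asarray(panel.is_spikein, dtype=bool)
    bio_idx = {g: i for i, g in enumerate(panel.gene_id)}
    for grp in design.groups:
        for m in grp.marker_gene_ids:
            if m not in bio_idx:
                raise ValueError(f"marker gene {m!r} not in panel")
            if spikes[bio_idx[m]]:
                raise ValueError(f"marker gene {m!r} is a spike-in")

    n_genes = len(panel.gene_id)
    n_cells = sum(g.n_cells for g in design.groups)
    rng = rng_for(seed, "counts")

    size_factors = rng.lognormal(mean=0.0, sigma=design.size_factor_sd, size=n_cells)
    base = np.where(spikes, 0.0, np.nan_to_num(panel.base_mean))

    mean = np.empty((n_genes, n_cells), dtype=float)
    cell_ids, groups = [], []
    col = 0
    for grp in design.groups:
        mult = np.ones(n_genes)
        for m in grp.marker_gene_ids:
            mult[bio_idx[m]] = grp.marker_multiplier
        for _ in range(grp.n_cells):
            mean[:, col] = base * mult * size_factors[col]
            cell_ids.append(f"{grp.name}_c{col + 1:04d}")
            groups.append(grp.name)
            col += 1
    mean[spikes, :] = np.nan_to_num(panel.spike_level)[spikes, None]

    counts = _nb_draw(rng, mean, noise.dispersion)
    detect = rng.random(mean.shape) < noise.p_detect(mean)
    counts = np.where(detect, counts, 0)

    values = pd.DataFrame(
        counts.astype(np.int64),
        index=pd.Index(list(panel.gene_id), name="gene_id"),
        columns=pd.Index(cell_ids, name="cell_id"),
    )
    cell_table = pd.DataFrame(
        {
            "patient": "P1",
            "tissue": groups,
            "well_type": "sample",
            "group": groups,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return CountMatrix(values, panel.gene_table(), cell_table)


def add_control_wells(matrix: CountMatrix, n_neg: int, n_pos: int, seed: int) -> CountMatrix:
    """Append blank (negative) and pseudo-bulk (positive) control wells.

    Negative wells carry near-zero biological counts (Poisson, mean 0.01 per
    gene) plus the full spike-in signal; positive wells are a depth-matched
    Poisson draw from the averaged pseudo-bulk profile of the sample cells.
    """
    if n_neg < 0 or n_pos < 0:
        raise ValueError("control well counts must be non-negative")
    if n_neg == 0 and n_pos == 0:
        return matrix
    rng = rng_for(seed, "controls")
    spikes = matrix.spike_mask.to_numpy()
    sample_cols = matrix.cell_table["well_type"] == "sample"
    sample_counts = matrix.values.loc[:, sample_cols.to_numpy()].to_numpy()
    spike_means = sample_counts[spikes].mean(axis=1) if sample_counts.size else np.zeros(spikes.sum())

    new_cols, new_ids, new_types = [], [], []
    for i in range(n_neg):
        col = np.zeros(matrix.n_genes, dtype=np.int64)
        col[~spikes] = rng.poisson(0.01, size=(~spikes).sum())
        col[spikes] = rng.poisson(spike_means)
        new_cols.append(col)
        new_ids.append(f"NEG{i + 1:02d}")
        new_types.append("neg_control")

    if n_pos > 0:
        bulk = sample_counts[~spikes].mean(axis=1)
        bulk_total = bulk.sum()
        target_depth = sample_counts[~spikes].sum(axis=0).mean()
        profile = bulk / bulk_total * target_depth if bulk_total > 0 else bulk
        for i in range(n_pos):
            col = np.zeros(matrix.n_genes, dtype=np.int64)
            col[~spikes] = rng.poisson(profile)
            col[spikes] = rng.poisson(spike_means)
            new_cols.append(col)
            new_ids.append(f"POS{i + 1:02d}")
            new_types.append("pos_control")

    extra = pd.DataFrame(
        np.column_stack(new_cols),
        index=matrix.values.index,
        columns=pd.Index(new_ids, name="cell_id"),
    )
    extra_cells = pd.DataFrame(
        {
            "patient": "NA",
            "tissue": "control",
            "well_type": new_types,
            "group": "control",
        },
        index=pd.Index(new_ids, name="cell_id"),
    )
    return CountMatrix(
        pd.concat([matrix.values, extra], axis=1),
        matrix.gene_table,
        pd.concat([matrix.cell_table, extra_cells]),
    )


def default_plate(seed: int, *, n_neg: int = 3, n_pos: int = 3) -> CountMatrix:
    """Desk-scale default plate: 108 biological genes + 12 spike-ins, 3 groups × 100 cells."""
    panel = build_panel(108, 12, seed)
    genes = [g for g in panel.gene_id if not g.startswith("ERCC-")]
    design = CellDesign(
        groups=[
            GroupDesign("G1", 100, genes[0:20], 4.0),
            GroupDesign("G2", 100, genes[20:40], 4.0),
            GroupDesign("G3", 100, genes[40:60], 4.0),
        ],
        size_factor_sd=0.25,
    )
    matrix = simulate_counts(panel, design, NoiseParams(), seed)
    return add_control_wells(matrix, n_neg, n_pos, seed)
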