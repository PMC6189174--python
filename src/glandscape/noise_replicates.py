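"""Spike-in technical-noise model and simulated technical replicates.

Spike-in transcripts enter every well at a fixed dilution, so across wells
their counts vary for technical reasons only. Two curves are fitted from
per-spike summary statistics:

* dropout — a logistic curve for the probability of detecting a transcript,
  as a function of log2(mean detected count + 1), fitted by binomial maximum
  likelihood with the slope constrained non-negative;
* variance — a least-squares line of log2(variance over detected wells) on
  log2(mean over detected wells), with predictions floored at the mean
  (Poisson floor), since counting noise alone already contributes var = mean.

A simulated technical replicate perturbs the observed counts under this
model: each positive entry x is zeroed with probability 1 − p_detect(x)
(dropout injection) and otherwise resampled from a negative binomial with
mean x and the fitted variance; each zero entry of gene g is recovered with a
probability chosen so the expected per-gene detection rate is preserved, the
recovered value drawn around the gene's detected-well mean. With noise
parameters at zero the replicate distribution collapses onto the source
matrix, so consensus structure measured across replicates reflects the
fitted technical noise and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from ._utils import spawn_seeds
from .errors import ConfigurationError, FitError, StateError
from .matrix_io import CountMatrix


@dataclass
class SpikeStats:
    """Per-spike detection and moment statistics over sample wells."""

    table: pd.DataFrame  # index spike_id; mean_detected, var_detected, detection_rate, n_wells, n_detected
    n_wells: int


@dataclass
class DropoutFit:
    midpoint: float  # m0 on the log2(mean+1) scale; -inf means no dropout
    slope: float

    def p_detect(self, counts: np.ndarray) -> np.ndarray:
        counts = np.asarray(counts, dtype=float)
        if np.isneginf(self.midpoint):
            return np.ones_like(counts)
        return expit(self.slope * (np.log2(counts + 1.0) - self.midpoint))


@dataclass
class VarianceFit:
    intercept: float  # c0 of log2 var = c0 + c1 log2 mean
    slope: float  # c1
    zero_variance: bool = False  # noiseless model: replicate == source

    def predict(self, mean: np.ndarray) -> np.ndarray:
        mean = np.asarray(mean, dtype=float)
        if self.zero_variance:
            return np.zeros_like(mean)
        with np.errstate(divide="ignore"):
            fitted = 2.0 ** (self.intercept + self.slope * np.log2(np.maximum(mean, 1e-300)))
        return np.maximum(fitted, mean)  # Poisson floor


@dataclass
class NoiseModel:
    dropout: DropoutFit
    variance: VarianceFit
    n_spikeins: int
    n_wells: int

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        """Zero-noise model: p_detect ≡ 1 and zero resampling variance."""
        return cls(
            dropout=DropoutFit(midpoint=-np.inf, slope=1.0),
            variance=VarianceFit(intercept=0.0, slope=1.0, zero_variance=True),
            n_spikeins=0,
            n_wells=0,
        )

    def to_dict(self) -> dict:
        return {
            "dropout": {"m0": self.dropout.midpoint, "b": self.dropout.slope},
            "variance": {"c0": self.variance.intercept, "c1": self.variance.slope},
            "n_spikeins": self.n_spikeins,
            "n_wells": self.n_wells,
        }


def spikein_stats(matrix: CountMatrix) -> SpikeStats:
    """Detection rate and detected-well moments per spike-in, over sample wells."""
    spike_ids = matrix.gene_table.index[matrix.spike_mask.to_numpy()]
    if len(spike_ids) == 0:
        raise ConfigurationError("no spike-in genes flagged in the matrix")
    sample_cols = (matrix.well_type == "sample").to_numpy()
    counts = matrix.values.loc[spike_ids].to_numpy()[:, sample_cols]
    n_wells = counts.shape[1]
    rows = []
    for i, spike in enumerate(spike_ids):
        row = counts[i]
        detected = row[row > 0]
        rows.append(
            {
                "mean_detected": detected.mean() if detected.size else np.nan,
                "var_detected": detected.var(ddof=1) if detected.size >= 2 else np.nan,
                "detection_rate": detected.size / n_wells if n_wells else np.nan,
                "n_wells": n_wells,
                "n_detected": detected.size,
            }
        )
    return SpikeStats(pd.DataFrame(rows, index=pd.Index(spike_ids, name="spike_id")), n_wells)


def fit_dropout(stats: SpikeStats) -> DropoutFit:
    """Binomial-likelihood logistic fit of detection rate vs log2(mean detected + 1)."""
    tab = stats.table
    usable = tab[tab["detection_rate"] > 0].dropna(subset=["mean_detected"])
    if len(usable) < 2:
        raise FitError(f"need >= 2 spikes with detections, have {len(usable)}")
    if (usable["detection_rate"] >= 1.0).all():
        return DropoutFit(midpoint=-np.inf, slope=1.0)  # no dropout observed

    x = np.log2(usable["mean_detected"].to_numpy() + 1.0)
    k = usable["n_detected"].to_numpy(dtype=float)
    n = usable["n_wells"].to_numpy(dtype=float)

    def nll(params):
        m0, b = params
        p = np.clip(expit(b * (x - m0)), 1e-12, 1 - 1e-12)
        return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))

    # crude midpoint start: x where observed rate crosses 0.5
    rate = k / n
    m0_start = float(np.interp(0.5, np.sort(rate), x[np.argsort(rate)]))
    best = None
    for b_start in (0.5, 1.5, 4.0):
        res = minimize(
            nll,
            x0=[m0_start, b_start],
            method="L-BFGS-B",
            bounds=[(-20.0, 40.0), (0.0, 50.0)],
        )
        if best is None or res.fun < best.fun:
            best = res
    return DropoutFit(midpoint=float(best.x[0]), slope=float(best.x[1]))


def fit_variance(stats: SpikeStats) -> VarianceFit:
    """Least-squares line of log2 detected-well variance on log2 detected-well mean."""
    tab = stats.table
    usable = tab[(tab["detection_rate"] > 0) & (tab["n_detected"] >= 2)].dropna(
        subset=["mean_detected", "var_detected"]
    )
    usable = usable[usable["var_detected"] > 0]
    if len(usable) < 3:
        raise FitError(f"need >= 3 spikes with a detected-well variance, have {len(usable)}")
    x = np.log2(usable["mean_detected"].to_numpy())
    y = np.log2(usable["var_detected"].to_numpy())
    slope, intercept = np.polyfit(x, y, 1)
    return VarianceFit(intercept=float(intercept), slope=float(slope))


def fit_noise_model(matrix: CountMatrix) -> NoiseModel:
    """Convenience: spike stats → dropout and variance fits in one call."""
    stats = spikein_stats(matrix)
    return NoiseModel(
        dropout=fit_dropout(stats),
        variance=fit_variance(stats),
        n_spikeins=len(stats.table),
        n_wells=stats.n_wells,
    )


def _nb_from_mean_var(
    rng: np.random.Generator, mean: np.ndarray, var: np.ndarray
) -> np.ndarray:
    """Draw NB(mean, var); Poisson where var <= mean; point mass where var == 0."""
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    out = np.rint(mean).astype(np.int64)  # var == 0: keep the value
    poisson = (var > 0) & (var <= mean)
    out[poisson] = rng.poisson(mean[poisson])
    nb = var > mean
    if nb.any():
        m, v = mean[nb], var[nb]
        size = m**2 / (v - m)
        p = size / (size + m)
        out[nb] = rng.negative_binomial(size, p)
    return out


def _truncated_nb_from_mean_var(
    rng: np.random.Generator, mean: np.ndarray, var: np.ndarray
) -> np.ndarray:
    """Zero-truncated NB(mean, var) draw, by redraw of zeros.

    Used for values that represent *detected* measurements: dropout is
    modelled by the explicit injection step, so the resampling distribution
    is conditioned on detection. After a few redraw rounds any residual zero
    is set to 1 (the smallest detectable count).
    """
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    out = _nb_from_mean_var(rng, mean, var)
    for _ in range(10):
        zeros = (out == 0) & (var > 0)
        if not zeros.any():
            break
        out[zeros] = _nb_from_mean_var(rng, mean[zeros], var[zeros])
    out[(out == 0) & (var > 0)] = 1
    return out


def simulate_replicate(matrix: CountMatrix, model: NoiseModel, seed: int) -> CountMatrix:
    """One simulated technical replicate of ``matrix`` under the fitted model."""
    if model is None or model.dropout is None or model.variance is None:
        raise StateError("noise model is not fitted")
    rng = np.random.default_rng(seed)
    x = matrix.values.to_numpy()
    n_genes, n_cells = x.shape
    out = np.zeros_like(x)

    pos = x > 0
    # positive entries: dropout injection, else NB resampling around x.
    # Injection is capped per gene so the expected number of injected zeros
    # never exceeds the gene's zero pool: together with the recovery rule
    # below this preserves the expected per-gene detection rate exactly.
    p_det = model.dropout.p_detect(x)
    n_pos_g = pos.sum(axis=1).astype(float)
    n_zero_g = x.shape[1] - n_pos_g
    expected_inject = ((1.0 - p_det) * pos).sum(axis=1)
    alpha = np.where(
        expected_inject > n_zero_g,
        n_zero_g / np.maximum(expected_inject, 1e-300),
        1.0,
    )
    inject_p = (1.0 - p_det) * alpha[:, None]
    keep = rng.random(x.shape) >= inject_p
    resample = pos & keep
    if resample.any():
        out[resample] = _truncated_nb_from_mean_var(
            rng, x[resample], model.variance.predict(x[resample])
        )

    # zero entries: detection-rate-preserving recovery per gene; the expected
    # number of recoveries equals the (capped) expected number of injections
    r = np.where(
        n_zero_g > 0,
        np.minimum(1.0, expected_inject * alpha / np.maximum(n_zero_g, 1)),
        0.0,
    )
    # recovery values are drawn around the injection-weighted mean of the
    # positive entries (the expected value of what dropout removes), which
    # keeps the perturbation mean-preserving per gene, not just rate-preserving
    inj_weight = (inject_p * pos).sum(axis=1)
    gene_mean = np.where(
        inj_weight > 0,
        (x * inject_p * pos).sum(axis=1) / np.maximum(inj_weight, 1e-300),
        np.where(n_pos_g > 0, (x * pos).sum(axis=1) / np.maximum(n_pos_g, 1), 0.0),
    )
    recover = (~pos) & (rng.random(x.shape) < r[:, None])
    if recover.any():
        means = np.broadcast_to(gene_mean[:, None], x.shape)[recover]
        out[recover] = _truncated_nb_from_mean_var(rng, means, model.variance.predict(means))

    return matrix.with_counts(out)


@dataclass
class ReplicateSet:
    """Deterministic generator of simulated technical replicates.

    Per-replicate seeds are derived from the master seed, so regenerating
    with the same master seed reproduces every replicate bit-exactly.
    """

    source: CountMatrix
    model: NoiseModel
    n_replicates: int
    master_seed: int

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        self._seeds = spawn_seeds(self.master_seed, self.n_replicates, "replicates")

    def __len__(self) -> int:
        return self.n_replicates

    def replicate(self, i: int) -> CountMatrix:
        return simulate_replicate(self.source, self.model, self._seeds[i])

    def __iter__(self):
        for i in range(self.n_replicates):
            yield self.replicate(i)


def simulate_replicates(
    matrix: CountMatrix, model: NoiseModel, n: int = 250, seed: int = 0
) -> ReplicateSet:
    """Set of ``n`` (default 250) simulated technical replicates."""
    return ReplicateSet(source=matrix, model=model, n_replicates=n, master_seed=seed)
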