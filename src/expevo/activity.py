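"""Active-gene calling by z-transformation of log2 RPKM (zFPKM-style).

The per-sample log2 RPKM density of a transcriptome is roughly a Gaussian of
actively transcribed genes with a left shoulder of background. Following the
half-Gaussian fit of Hart et al., the mode mu of the kernel density estimate
locates the active peak, and the spread of values above the mode gives the
scale: with U the mean of log2 values greater than mu,

    sigma = (U - mu) * sqrt(pi / 2),

the standard deviation of a half-normal whose mean above the mode is U - mu.
z = (log2 RPKM - mu) / sigma; genes whose z averaged over developmental
stages is >= -3 are called actively transcribed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .io import ExpressionMatrix, ScogMap

MIN_POSITIVE_VALUES = 50
KDE_GRID_POINTS = 512
Z_SENTINEL = -np.inf  # z of RPKM == 0: arbitrarily small


class DegenerateDistributionError(ValueError):
    """Expression column too uniform or too sparse to fit a density."""


@dataclass(frozen=True)
class ZFitParams:
    """Half-Gaussian fit of one stage's log2 RPKM density (log2 units)."""

    mu: float  # mode of the log2 density
    sigma: float  # half-Gaussian scale
    U: float  # mean of log2 values above the mode

    def __post_init__(self):
        if not (self.sigma > 0):
            raise DegenerateDistributionError("sigma must be positive")
        if self.U < self.mu:
            raise DegenerateDistributionError("U must be >= mu")

    def z(self, rpkm) -> np.ndarray:
        """z-score of RPKM values; zeros map to the -inf sentinel."""
        rpkm = np.asarray(rpkm, dtype=float)
        with np.errstate(divide="ignore"):
            return np.where(
                rpkm > 0, (np.log2(np.maximum(rpkm, 1e-300)) - self.mu) / self.sigma,
                Z_SENTINEL,
            )


def fit_z_params(stage_values) -> ZFitParams:
    """Fit the half-Gaussian z-transform to one stage column of RPKM values.

    Zeros are excluded from the density fit (log2 undefined); they re-enter
    activity calls through the sentinel. The mode is located on a 512-point
    grid spanning the data range +/- 3 Silverman bandwidths; ties take the
    smallest mu.
    """
    vals = np.asarray(stage_values, dtype=float)
    pos = vals[vals > 0]
    if pos.size < MIN_POSITIVE_VALUES:
        raise DegenerateDistributionError(
            f"need >= {MIN_POSITIVE_VALUES} positive values, got {pos.size}"
        )
    logv = np.log2(pos)
    if np.ptp(logv) == 0:
        raise DegenerateDistributionError("all positive values identical")
    kde = gaussian_kde(logv, bw_method="silverman")
    h = math.sqrt(float(kde.covariance[0, 0]))
    grid = np.linspace(logv.min() - 3 * h, logv.max() + 3 * h, KDE_GRID_POINTS)
    dens = kde(grid)
    mu = float(grid[int(np.argmax(dens))])  # argmax returns first (smallest) tie
    above = logv[logv > mu]
    if above.size == 0:
        raise DegenerateDistributionError("no values above the density mode")
    U = float(above.mean())
    sigma = (U - mu) * math.sqrt(math.pi / 2.0)
    if sigma <= 0:
        raise DegenerateDistributionError("fitted sigma is zero")
    return ZFitParams(mu=mu, sigma=sigma, U=U)


def z_transform(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-stage z-scores for a whole expression matrix (genes x stages).

    Each stage column is fitted independently, matching per-sample zFPKM
    semantics. RPKM = 0 becomes the -inf sentinel.
    """
    out = {}
    for stage in matrix.stages:
        col = matrix.data[stage].to_numpy(dtype=float)
        try:
            params = fit_z_params(col)
        except DegenerateDistributionError as exc:
            raise DegenerateDistributionError(
                f"{matrix.species}, stage {stage!r}: {exc}"
            ) from exc
        out[stage] = params.z(col)
    return pd.DataFrame(out, index=matrix.data.index)


@dataclass(frozen=True)
class ActivityCall:
    gene_id: str
    mean_z: float
    active: bool


def call_activity(
    zscores: pd.DataFrame, z_threshold: float = -3.0, per_stage: bool = False
) -> pd.DataFrame:
    """Call genes active from their stage z-scores.

    Default rule: mean z over stages >= threshold (the sentinel -inf
    dominates the mean, so an all-zero gene is inactive). With
    ``per_stage=True`` a gene is instead inactive only when *every* stage is
    below the threshold, i.e. active iff max z >= threshold.

    Returns a DataFrame indexed by gene id with columns mean_z, active.
    """
    mean_z = zscores.mean(axis=1)
    if per_stage:
        active = zscores.max(axis=1) >= z_threshold
    else:
        active = mean_z >= z_threshold
    return pd.DataFrame({"mean_z": mean_z, "active": active})


def filter_scogs(
    scog_map: ScogMap, activity_by_species: dict[str, pd.DataFrame]
) -> tuple[ScogMap, list[str]]:
    """Exclude clusters containing one or more inactive member genes.

    Returns (retained map, excluded cluster ids); the two partition the
    input. Raises if any member gene lacks an activity call.
    """
    excluded: list[str] = []
    for cid in scog_map.cluster_ids:
        drop = False
        for sp in scog_map.species:
            gene = scog_map.member(cid, sp)
            calls = activity_by_species.get(sp)
            if calls is None or gene not in calls.index:
                raise KeyError(f"no activity call for gene {gene!r} ({sp})")
            if not bool(calls.at[gene, "active"]):
                drop = True
        if drop:
            excluded.append(cid)
    retained_ids = [c for c in scog_map.cluster_ids if c not in set(excluded)]
    return scog_map.restrict(retained_ids), excluded


def percent(n: int, total: int, ndigits: int = 1) -> float:
    """Percentage of a count, rounded as printed in summary tables."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * n / total, ndigits)
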