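"""Recurrent-aberration detection from kernel-smoothed aggregate profiles.

For one group of tumors, positive and negative log2 values are summed
separately across samples per clone ("aggregate" gain and loss profiles),
then smoothed with a Gaussian kernel onto a regular genomic grid — the
kernel-smoothed estimate (KSE). Significance comes from a randomization
null: the clone-to-position assignment is permuted (one shared permutation
per randomized instance, so per-locus sample correlation is preserved), the
KSE recomputed, and the genome-wide maximum (gain) / minimum (loss)
recorded. The (1 - alpha) point of this max-statistic distribution is a
family-wise-error-corrected significance threshold; runs of grid points
beyond it are the significantly recurrent regions. A pointwise
Bonferroni-corrected variant over the same randomized instances is offered
as an alternative correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from math import ceil

import numpy as np
import pandas as pd

from .io import AcghDataset, CloneMap
from .kernel import grid_for, smoothing_matrix

DEFAULT_KERNEL_WIDTH_BP = 1_000_000
DEFAULT_GRID_SPACING_BP = 50_000


@dataclass
class KseProfile:
    """Genome-wide smoothed gain/loss estimate on a regular grid.

    ``grid`` has columns chromosome, bp, global_bp; kse_gain >= 0 and
    kse_loss <= 0 everywhere. Thresholds are absent (None) until a
    randomization-null run attaches them.
    """

    grid: pd.DataFrame
    kse_gain: np.ndarray
    kse_loss: np.ndarray
    kernel_width_bp: float
    grid_spacing_bp: int
    n_samples: int
    threshold_gain: float | None = None
    threshold_loss: float | None = None
    n_permutations: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.copy()
        df["kse_gain"] = self.kse_gain
        df["kse_loss"] = self.kse_loss
        df["threshold_gain"] = self.threshold_gain if self.threshold_gain is not None else np.nan
        df["threshold_loss"] = self.threshold_loss if self.threshold_loss is not None else np.nan
        return df


def aggregate_profile(dataset: AcghDataset, sign: str) -> np.ndarray:
    """Per-clone sum over samples of the positive ('gain') or negative
    ('loss') part of log2. Missing values contribute zero."""
    x = np.nan_to_num(dataset.log2, nan=0.0)
    if sign == "gain":
        return np.maximum(x, 0.0).sum(axis=0)
    if sign == "loss":
        return np.minimum(x, 0.0).sum(axis=0)
    raise ValueError("sign must be 'gain' or 'loss'")


def kse(
    aggregate: np.ndarray,
    clone_map: CloneMap,
    grid_spacing_bp: int = DEFAULT_GRID_SPACING_BP,
    kernel_width_bp: float = DEFAULT_KERNEL_WIDTH_BP,
    truncation: float | None = 5.0,
    normalize: bool = False,
    grid: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Smooth a per-clone aggregate onto the genomic grid (one sign).

    Returns (grid, values). Smoothing never crosses chromosome boundaries;
    see :mod:`metacgh.kernel` for the truncation contract.
    """
    if grid is None:
        grid = grid_for(clone_map.genome, grid_spacing_bp, list(pd.unique(clone_map.chromosome)))
    W = smoothing_matrix(clone_map.chromosome, clone_map.position_bp, grid,
                         kernel_width_bp, truncation, normalize)
    return grid, W @ np.asarray(aggregate, dtype=float)


def kse_profile(
    dataset: AcghDataset,
    grid_spacing_bp: int = DEFAULT_GRID_SPACING_BP,
    kernel_width_bp: float = DEFAULT_KERNEL_WIDTH_BP,
    truncation: float | None = 5.0,
    normalize: bool = False,
) -> KseProfile:
    """Gain and loss KSEs of a dataset on one shared grid."""
    cm = dataset.clone_map
    grid = grid_for(cm.genome, grid_spacing_bp, list(pd.unique(cm.chromosome)))
    W = smoothing_matrix(cm.chromosome, cm.position_bp, grid, kernel_width_bp, truncation, normalize)
    gain = W @ aggregate_profile(dataset, "gain")
    loss = W @ aggregate_profile(dataset, "loss")
    return KseProfile(grid, gain, loss, kernel_width_bp, grid_spacing_bp, dataset.n_samples)


def _null_extrema(
    aggregate: np.ndarray,
    clone_map: CloneMap,
    grid: pd.DataFrame,
    kernel_width_bp: float,
    n_permutations: int,
    rng: np.random.Generator,
    minima: bool,
    truncation: float | None = 5.0,
    chunk: int = 100,
) -> np.ndarray:
    """Genome-wide max (or min) KSE for randomized clone->position
    assignments of the aggregate."""
    W = smoothing_matrix(clone_map.chromosome, clone_map.position_bp, grid,
                         kernel_width_bp, truncation)
    a = np.asarray(aggregate, dtype=float)
    out = np.empty(n_permutations)
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        perms = np.stack([rng.permutation(len(a)) for _ in range(m)], axis=1)
        K = W @ a[perms]  # n_grid x m
        out[done:done + m] = K.min(axis=0) if minima else K.max(axis=0)
        done += m
    return out


def _order_statistic_threshold(values: np.ndarray, alpha: float, upper: bool) -> float:
    """(1-alpha) point of a randomization distribution via the
    ceil((1-alpha)(m+1)) order statistic; alpha=1 degenerates to the extreme."""
    m = len(values)
    k = max(1, ceil((1.0 - alpha) * (m + 1)))
    if k > m:
        raise ValueError(f"n_permutations={m} too small for alpha={alpha}")
    srt = np.sort(values)
    return float(srt[k - 1]) if upper else float(srt[m - k])


def kse_null_threshold(
    dataset: AcghDataset,
    sign: str,
    grid_spacing_bp: int = DEFAULT_GRID_SPACING_BP,
    kernel_width_bp: float = DEFAULT_KERNEL_WIDTH_BP,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    truncation: float | None = 5.0,
) -> float:
    """Family-wise-error-corrected KSE significance threshold for one sign.

    Each randomized instance permutes the clone-to-position assignment once,
    shared across samples (equivalently: permutes the aggregate over clone
    positions), and records the genome-wide extremum of the resulting KSE;
    the threshold is the (1 - alpha) point of that extremum distribution.
    """
    if n_permutations < 20:
        raise ValueError("n_permutations must be at least 20")
    cm = dataset.clone_map
    grid = grid_for(cm.genome, grid_spacing_bp, list(pd.unique(cm.chromosome)))
    agg = aggregate_profile(dataset, sign)
    rng = np.random.default_rng(seed)
    if sign == "gain":
        maxima = _null_extrema(agg, cm, grid, kernel_width_bp, n_permutations, rng,
                               minima=False, truncation=truncation)
        return _order_statistic_threshold(maxima, alpha, upper=True)
    minima = _null_extrema(agg, cm, grid, kernel_width_bp, n_permutations, rng,
                           minima=True, truncation=truncation)
    return _order_statistic_threshold(minima, alpha, upper=False)


def with_null_thresholds(
    profile: KseProfile,
    dataset: AcghDataset,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> KseProfile:
    """Attach gain and loss thresholds (separate extremum nulls) to a profile."""
    tg = kse_null_threshold(dataset, "gain", profile.grid_spacing_bp, profile.kernel_width_bp,
                            n_permutations, alpha, seed)
    tl = kse_null_threshold(dataset, "loss", profile.grid_spacing_bp, profile.kernel_width_bp,
                            n_permutations, alpha, seed + 1)
    return replace(profile, threshold_gain=tg, threshold_loss=tl, n_permutations=n_permutations)


def kse_pointwise_pvalues(
    dataset: AcghDataset,
    sign: str,
    grid_spacing_bp: int = DEFAULT_GRID_SPACING_BP,
    kernel_width_bp: float = DEFAULT_KERNEL_WIDTH_BP,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bonferroni alternative: per-grid-point empirical p-values against the
    same clone-position randomization null, with p_bonferroni = min(1, p * n_grid)."""
    cm = dataset.clone_map
    grid = grid_for(cm.genome, grid_spacing_bp, list(pd.unique(cm.chromosome)))
    W = smoothing_matrix(cm.chromosome, cm.position_bp, grid, kernel_width_bp, 5.0)
    agg = aggregate_profile(dataset, sign)
    obs = W @ agg
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(grid), dtype=np.int64)
    done, chunk = 0, 100
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        perms = np.stack([rng.permutation(len(agg)) for _ in range(m)], axis=1)
        K = W @ agg[perms]
        if sign == "gain":
            exceed += (K >= obs[:, None]).sum(axis=1)
        else:
            exceed += (K <= obs[:, None]).sum(axis=1)
        done += m
    p = (exceed + 1) / (n_permutations + 1)
    out = grid.copy()
    out["kse"] = obs
    out["p_value"] = p
    out["p_bonferroni"] = np.minimum(1.0, p * len(grid))
    return out


def _runs_to_regions(grid: pd.DataFrame, above: np.ndarray, sign: str,
                     values: np.ndarray, spacing_bp: int) -> list[dict]:
    regions = []
    chrom = grid["chromosome"].to_numpy()
    bp = grid["bp"].to_numpy()
    # break runs at chromosome boundaries
    change = np.flatnonzero((above[1:] != above[:-1]) | (chrom[1:] != chrom[:-1])) + 1
    bounds = np.concatenate([[0], change, [len(above)]])
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if not above[lo]:
            continue
        seg = slice(lo, hi)
        peak = values[seg].max() if sign == "gain" else values[seg].min()
        regions.append({
            "chromosome": chrom[lo],
            "start_bp": int(bp[lo]),
            "end_bp": int(bp[hi - 1] + spacing_bp),
            "sign": sign,
            "peak": float(peak),
        })
    return regions


def significant_regions(profile: KseProfile) -> pd.DataFrame:
    """Maximal grid runs beyond the attached thresholds, as half-open bp
    intervals with peak KSE. Requires thresholds (a prior null run)."""
    if profile.threshold_gain is None or profile.threshold_loss is None:
        raise ValueError("profile has no thresholds; run with_null_thresholds first")
    regions = _runs_to_regions(profile.grid, profile.kse_gain > profile.threshold_gain,
                               "gain", profile.kse_gain, profile.grid_spacing_bp)
    regions += _runs_to_regions(profile.grid, profile.kse_loss < profile.threshold_loss,
                                "loss", profile.kse_loss, profile.grid_spacing_bp)
    return pd.DataFrame(regions, columns=["chromosome", "start_bp", "end_bp", "sign", "peak"])


def kse_correlation(profile_a: KseProfile, profile_b: KseProfile, sign: str) -> float:
    """Pearson correlation between two groups' KSEs (same grid, one sign).
    Returns NaN (with a warning) if either profile has zero variance."""
    if not np.array_equal(profile_a.grid["global_bp"].to_numpy(),
                          profile_b.grid["global_bp"].to_numpy()):
        raise ValueError("profiles are on different grids")
    a = profile_a.kse_gain if sign == "gain" else profile_a.kse_loss
    b = profile_b.kse_gain if sign == "gain" else profile_b.kse_loss
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero-variance KSE profile; correlation undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
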