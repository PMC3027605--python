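"""Differential-aberration detection between two tumor groups.

Each tumor's signed log2 profile is smoothed individually onto a fixed grid
(default spacing 50 kb). At every grid point the two groups are compared
with a signal-to-noise ratio (SNR): the absolute difference of group means
divided by the sum of the within-group standard deviations — a t-like
statistic. Significance comes from permuting the group labels (default 1000
times, group sizes preserved): for a candidate threshold t the estimated
false discovery rate is

    FDR(t) = mean_perms #{g : SNR_perm(g) > t} / max(1, #{g : SNR_obs(g) > t})

capped at 1 (a plug-in estimator in the SAM lineage) and made monotone
(non-increasing in t) by a conservative running maximum over larger
thresholds. The q-level threshold is the smallest
observed SNR value with FDR <= q; grid runs above it are the significantly
differentially aberrant regions.

The SNR is invariant to row-normalization of the smoother (the same
per-grid-point factor scales numerator and denominator), so per-tumor
smoothing defaults to the normalized (local weighted average) kernel, which
preserves constant profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field

from .io import AcghDataset
from .kernel import grid_for, smoothing_matrix
from .kcsmart import DEFAULT_KERNEL_WIDTH_BP, _runs_to_regions

DEFAULT_GRID_SPACING_BP = 50_000


@dataclass
class SmoothedSampleMatrix:
    """Per-tumor smoothed log2 profiles on a fixed grid (samples x grid)."""

    grid: pd.DataFrame
    values: np.ndarray
    kernel_width_bp: float
    grid_spacing_bp: int
    sample_ids: list[str]
    groups: np.ndarray


@dataclass
class SnrProfile:
    """Observed SNR per grid point with permutation-FDR thresholds.

    ``thresholds[q]`` is None when no SNR value attains estimated FDR <= q.
    ``fdr_curve`` maps candidate thresholds (ascending) to estimated FDR
    (non-increasing).
    """

    grid: pd.DataFrame
    snr: np.ndarray
    group_labels: tuple[str, str]
    grid_spacing_bp: int
    n_permutations: int
    fdr_curve: pd.DataFrame = field(default_factory=pd.DataFrame)
    thresholds: dict[float, float | None] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.copy()
        df["snr"] = self.snr
        for q, t in sorted(self.thresholds.items()):
            df[f"flag_fdr{q:g}"] = (self.snr > t) if t is not None else False
        return df


def union_labels(groups: np.ndarray, union: dict[str, tuple[str, ...]]) -> np.ndarray:
    """Relabel groups, mapping each union member to the union's name;
    e.g. ``{"rest": ("PM", "M0")}`` merges PM and M0 into 'rest'."""
    out = np.asarray(groups, dtype=object).copy()
    for name, members in union.items():
        out[np.isin(out, members)] = name
    return out


def smooth_samples(
    dataset: AcghDataset,
    grid_spacing_bp: int = DEFAULT_GRID_SPACING_BP,
    kernel_width_bp: float = DEFAULT_KERNEL_WIDTH_BP,
    truncation: float | None = 5.0,
    normalize: bool = True,
) -> SmoothedSampleMatrix:
    """Smooth each tumor's signed log2 vector onto the grid.

    Missing values contribute zero weight mass (absent evidence; the row
    normalization is shared across samples).
    """
    cm = dataset.clone_map
    grid = grid_for(cm.genome, grid_spacing_bp, list(pd.unique(cm.chromosome)))
    W = smoothing_matrix(cm.chromosome, cm.position_bp, grid, kernel_width_bp,
                         truncation, normalize)
    values = np.nan_to_num(dataset.log2, nan=0.0) @ W.T.tocsr()
    return SmoothedSampleMatrix(grid, values, kernel_width_bp, grid_spacing_bp,
                                list(dataset.sample_ids), dataset.groups)


def _group_moments(values: np.ndarray, member: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and (n-1)-denominator sd over the rows selected by ``member``."""
    n = member.sum()
    sub = values[member]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    return mean, sd


def _snr_from_moments(mean_a, sd_a, mean_b, sd_b) -> np.ndarray:
    num = np.abs(mean_a - mean_b)
    den = sd_a + sd_b
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = num / den
    # zero variance in both groups: equal means -> 0, unequal -> +inf sentinel
    snr = np.where(den == 0, np.where(num == 0, 0.0, np.inf), snr)
    return snr


def snr(smoothed: SmoothedSampleMatrix, labels: np.ndarray, group_a: str, group_b: str) -> np.ndarray:
    """Per-grid-point signal-to-noise ratio between two groups:
    |mean_A - mean_B| / (sd_A + sd_B)."""
    labels = np.asarray(labels, dtype=object)
    in_a, in_b = labels == group_a, labels == group_b
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("each compared group needs at least 2 samples")
    ma, sa = _group_moments(smoothed.values, in_a)
    mb, sb = _group_moments(smoothed.values, in_b)
    return _snr_from_moments(ma, sa, mb, sb)


def _permuted_snr_exceedances(
    values: np.ndarray,
    n_a: int,
    candidates: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
    chunk: int = 100,
) -> np.ndarray:
    """For each candidate threshold, total count over permutations of grid
    points whose permuted SNR exceeds it. ``values`` holds only the samples
    of the two compared groups; each permutation draws a fresh size-n_a
    subset as pseudo-group A."""
    n, n_grid = values.shape
    sq = values * values
    totals = np.zeros(len(candidates), dtype=np.int64)
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        pick = np.zeros((m, n), dtype=float)
        for i in range(m):
            pick[i, rng.permutation(n)[:n_a]] = 1.0
        n_b = n - n_a
        sum_a = pick @ values
        sum_sq_a = pick @ sq
        sum_b = values.sum(axis=0) - sum_a
        sum_sq_b = sq.sum(axis=0) - sum_sq_a
        mean_a, mean_b = sum_a / n_a, sum_b / n_b
        var_a = np.maximum(sum_sq_a - n_a * mean_a**2, 0.0) / (n_a - 1)
        var_b = np.maximum(sum_sq_b - n_b * mean_b**2, 0.0) / (n_b - 1)
        s = _snr_from_moments(mean_a, np.sqrt(var_a), mean_b, np.sqrt(var_b))
        finite = s[np.isfinite(s)]
        # counts of permuted values strictly above each candidate
        totals += len(finite) - np.searchsorted(np.sort(finite), candidates, side="right")
        totals += np.int64((~np.isfinite(s)).sum())  # +inf sentinels exceed everything
        done += m
    return totals


def permutation_fdr(
    smoothed: SmoothedSampleMatrix,
    labels: np.ndarray,
    group_a: str,
    group_b: str,
    n_permutations: int = 1000,
    seed: int = 0,
    qs: tuple[float, ...] = (0.01, 0.05),
) -> SnrProfile:
    """Observed SNR with permutation-of-labels FDR thresholds.

    Labels are permuted uniformly at random with group sizes preserved;
    samples outside the two groups are ignored. Reproducible from ``seed``.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be at least 100")
    labels = np.asarray(labels, dtype=object)
    obs = snr(smoothed, labels, group_a, group_b)
    keep = np.isin(labels, [group_a, group_b])
    values = smoothed.values[keep]
    n_a = int((labels[keep] == group_a).sum())

    finite_obs = obs[np.isfinite(obs)]
    candidates = np.unique(finite_obs)  # ascending; exact step function of obs values
    rng = np.random.default_rng(seed)
    exceed_tot = _permuted_snr_exceedances(values, n_a, candidates, n_permutations, rng)

    obs_sorted = np.sort(finite_obs)
    n_inf = int(np.isinf(obs).sum())
    r = (len(obs_sorted) - np.searchsorted(obs_sorted, candidates, side="right")) + n_inf
    v_bar = exceed_tot / n_permutations
    fdr = np.minimum(1.0, v_bar / np.maximum(r, 1))
    # conservative monotone envelope: FDR(t) = max over t' >= t of the raw
    # estimate, so the curve is non-increasing in the threshold
    fdr = np.maximum.accumulate(fdr[::-1])[::-1]

    thresholds: dict[float, float | None] = {}
    for q in qs:
        ok = np.flatnonzero(fdr <= q)
        thresholds[q] = float(candidates[ok[0]]) if len(ok) else None

    curve = pd.DataFrame({"threshold": candidates, "fdr": fdr})
    return SnrProfile(smoothed.grid, obs, (group_a, group_b), smoothed.grid_spacing_bp,
                      n_permutations, curve, thresholds)


def differential_regions(profile: SnrProfile, q: float) -> pd.DataFrame:
    """Maximal grid runs with SNR above the q-level FDR threshold, as
    half-open bp intervals with peak SNR."""
    if q not in profile.thresholds:
        raise ValueError(f"no threshold computed for q={q}")
    t = profile.thresholds[q]
    if t is None:
        raise ValueError(f"FDR {q} threshold unattained (estimated FDR never fell below {q})")
    regions = _runs_to_regions(profile.grid, profile.snr > t, "gain", profile.snr,
                               profile.grid_spacing_bp)
    df = pd.DataFrame(regions, columns=["chromosome", "start_bp", "end_bp", "sign", "peak"])
    return df.drop(columns="sign").assign(q=q)
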