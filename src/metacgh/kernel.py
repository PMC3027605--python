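"""Gaussian kernel smoothing of per-clone signals onto a genomic grid.

The smoother is a grid x clones weight matrix W with
``W[g, c] = exp(-(x_g - p_c)^2 / (2 w^2))`` for clones on the same chromosome
as grid point g, and 0 across chromosome boundaries. Evaluation is truncated
beyond ``truncation`` kernel widths (default 4, per-term weight < 3.4e-4);
``truncation=None`` evaluates exactly. The default smoother is unnormalized
(a kernel-weighted sum, linear in the input); ``normalize=True`` divides each
row by its weight sum, turning it into a local weighted average that
preserves constants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

from .genome import Genome, make_grid


def smoothing_matrix(
    clone_chromosome: np.ndarray,
    clone_position_bp: np.ndarray,
    grid: pd.DataFrame,
    kernel_width_bp: float,
    truncation: float | None = 5.0,
    normalize: bool = False,
) -> sparse.csr_matrix:
    """Build the (n_grid x n_clones) Gaussian weight matrix.

    ``grid`` is a DataFrame with columns chromosome and bp (see
    :func:`metacgh.genome.make_grid`). Clones must be sorted by position
    within each chromosome (CloneMap order).
    """
    if kernel_width_bp <= 0:
        raise ValueError("kernel_width_bp must be positive")
    clone_chromosome = np.asarray(clone_chromosome)
    clone_position_bp = np.asarray(clone_position_bp, dtype=float)
    n_clones = len(clone_position_bp)
    n_grid = len(grid)

    rows, cols, vals = [], [], []
    grid_chrom = grid["chromosome"].to_numpy()
    grid_bp = grid["bp"].to_numpy(dtype=float)
    for chrom in pd.unique(grid_chrom):
        g_idx = np.flatnonzero(grid_chrom == chrom)
        c_idx = np.flatnonzero(clone_chromosome == chrom)
        if not len(g_idx) or not len(c_idx):
            continue
        pos = clone_position_bp[c_idx]
        x = grid_bp[g_idx]
        if truncation is None:
            lo = np.zeros(len(x), dtype=np.int64)
            hi = np.full(len(x), len(pos), dtype=np.int64)
        else:
            half = truncation * kernel_width_bp
            lo = np.searchsorted(pos, x - half, side="left")
            hi = np.searchsorted(pos, x + half, side="right")
        counts = hi - lo
        keep = counts > 0
        if not keep.any():
            continue
        g_rep = np.repeat(g_idx[keep], counts[keep])
        # column indices: for each grid point the clone run [lo, hi)
        offsets = np.concatenate([np.arange(l, h) for l, h in zip(lo[keep], hi[keep])])
        c_cols = c_idx[offsets]
        d = grid_bp[g_rep] - clone_position_bp[c_cols]
        w = np.exp(-(d * d) / (2.0 * kernel_width_bp**2))
        rows.append(g_rep)
        cols.append(c_cols)
        vals.append(w)

    if rows:
        mat = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_grid, n_clones),
        )
    else:
        mat = sparse.csr_matrix((n_grid, n_clones))
    if normalize:
        rowsum = np.asarray(mat.sum(axis=1)).ravel()
        inv = np.divide(1.0, rowsum, out=np.zeros_like(rowsum), where=rowsum > 0)
        mat = sparse.diags(inv) @ mat
    return mat.tocsr()


def grid_for(genome: Genome, spacing_bp: int, chromosomes: list[str] | None = None) -> pd.DataFrame:
    return make_grid(genome, spacing_bp, chromosomes)
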