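"""Functional connectivity density (FCD) mapping.

For every seed voxel, Pearson correlations with all other in-mask voxels are
thresholded at the minimal r whose single-connection p-value survives
Bonferroni correction.  Global FCD is the number of suprathreshold (positive)
connections; local FCD is the size (minus the seed) of the contiguous cluster
of suprathreshold voxels grown from the seed; long-range FCD is the
difference.  The three maps are finally z-scored across gray-matter voxels.

The seed-by-seed correlation is computed in blocks so memory stays bounded;
the output is identical to the naive all-pairs correlation matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .errors import DataError, InfeasibleThresholdError, InsufficientDataError
from .io_core import BoldRun, ScalarMap
from .spectral_alff import normalize_map

log = logging.getLogger("neurotau")

_STRUCTURES = {"face6": 1, "edge18": 2, "corner26": 3}


@dataclass(frozen=True)
class FCDTriple:
    """Local, long-range and global FCD maps plus the thresholding metadata."""

    local: ScalarMap
    long_range: ScalarMap
    global_: ScalarMap
    r_threshold: float
    alpha: float
    n_tests: int
    zscored: bool


def correlation_threshold(T: int, alpha: float, n_tests: int) -> float:
    """Minimal |r| significant at two-sided alpha after Bonferroni over n_tests.

    Uses the exact t-transform t = r sqrt((T-2)/(1-r^2)) with df = T-2.
    """
    if T < 4:
        raise DataError(f"need T >= 4, got {T}")
    if not 0 < alpha < 1:
        raise DataError(f"alpha must be in (0,1), got {alpha}")
    if n_tests < 1:
        raise DataError(f"n_tests must be >= 1, got {n_tests}")
    df = T - 2
    p_corr = alpha / n_tests
    t_crit = stats.t.isf(p_corr / 2.0, df)
    r = float(t_crit / np.sqrt(df + t_crit**2))
    if not np.isfinite(r) or r >= 1.0 - 1e-9:
        raise InfeasibleThresholdError(
            f"corrected alpha {p_corr:g} requires |r| >= 1 at T={T}"
        )
    return r


def compute_fcd(
    run: BoldRun,
    alpha: float = 0.05,
    family: str = "per_seed",
    neighborhood: str = "face6",
    zscore: bool = True,
    chunk_size: int = 512,
) -> FCDTriple:
    """Local / long-range / global FCD for every in-mask voxel.

    ``family`` sets the Bonferroni family size: ``per_seed`` uses
    n_voxels - 1 (one seed's tests), ``all_pairs`` uses n(n-1)/2.
    Degenerate (zero-variance) voxels are excluded from both seed and target
    sets and flagged missing in the output maps.
    """
    if family not in ("per_seed", "all_pairs"):
        raise DataError(f"unknown family {family!r}")
    if neighborhood not in _STRUCTURES:
        raise DataError(f"unknown neighborhood {neighborhood!r}")
    mask = run.mask
    n_all = mask.n_voxels
    if n_all < 2:
        raise InsufficientDataError("FCD needs at least 2 voxels")
    T = run.n_timepoints

    d = run.data - run.data.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", d, d)
    scale = np.abs(run.data).max(axis=1)
    ok = ss > (1e-12 * np.maximum(scale, 1e-300)) ** 2 * T
    n = int(ok.sum())
    if n < 2:
        raise InsufficientDataError("fewer than 2 non-degenerate voxels")
    if n < n_all:
        log.info("FCD: excluding %d degenerate voxels", n_all - n)

    n_tests = n - 1 if family == "per_seed" else n * (n - 1) // 2
    r_thr = correlation_threshold(T, alpha, n_tests)

    z = np.zeros_like(d)
    z[ok] = d[ok] / np.sqrt(ss[ok])[:, None]

    structure = ndimage.generate_binary_structure(3, _STRUCTURES[neighborhood])
    shape = mask.grid.shape
    flat_idx = mask.flat_indices

    glob = np.full(n_all, np.nan)
    loc = np.full(n_all, np.nan)
    ok_idx = np.flatnonzero(ok)
    conn_vol = np.zeros(int(np.prod(shape)), dtype=bool)
    for start in range(0, ok_idx.size, chunk_size):
        seeds = ok_idx[start : start + chunk_size]
        r_block = z[seeds] @ z[ok].T  # (chunk, n)
        for row, seed in enumerate(seeds):
            conn = r_block[row] > r_thr
            # drop the seed's self-correlation
            self_pos = np.searchsorted(ok_idx, seed)
            conn[self_pos] = False
            glob[seed] = conn.sum()
            # region-grow the suprathreshold cluster containing the seed
            conn_vol[:] = False
            conn_vol[flat_idx[ok_idx[conn]]] = True
            conn_vol[flat_idx[seed]] = True
            labels, _ = ndimage.label(conn_vol.reshape(shape), structure=structure)
            seed_label = labels.ravel()[flat_idx[seed]]
            loc[seed] = (labels == seed_label).sum() - 1
    long_range = glob - loc

    def _map(values, name):
        return ScalarMap(values=values, mask=mask, name=name, units="count")

    local_m = _map(loc, "fcd_local")
    long_m = _map(long_range, "fcd_long_range")
    glob_m = _map(glob, "fcd_global")
    if zscore:
        local_m = normalize_map(local_m, "zscore")
        long_m = normalize_map(long_m, "zscore")
        glob_m = normalize_map(glob_m, "zscore")
    return FCDTriple(
        local=local_m,
        long_range=long_m,
        global_=glob_m,
        r_threshold=r_thr,
        alpha=alpha,
        n_tests=n_tests,
        zscored=zscore,
    )
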