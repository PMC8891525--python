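"""Dominance analysis: all-subsets decomposition of a regression R^2.

General dominance of predictor i is the average, over subset sizes
s = 0..p-1, of the mean incremental R^2 obtained by adding i to each subset
of the other predictors of size s (with R^2 of the empty model = 0).  The
general dominance values sum exactly to the full-model R^2; percentages
express each predictor's share of that total.

Subsets are enumerated exhaustively (p <= 12) with the subset R^2 memoized
by predictor bitmask, so the decomposition is exact rather than approximate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import CollinearityError, DataError, InsufficientDataError
from .io_core import ScalarMap

MAX_PREDICTORS = 12


@dataclass(frozen=True)
class DominanceResult:
    predictors: tuple[str, ...]
    general_dominance: np.ndarray
    percentage: np.ndarray
    total_r2: float
    n_models: int

    def as_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "general_dominance": self.general_dominance.tolist(),
            "percentage": self.percentage.tolist(),
            "total_r2": self.total_r2,
            "n_models": self.n_models,
        }


def _subset_r2(cov_xx: np.ndarray, cov_xy: np.ndarray, var_y: float, subset) -> float:
    """R^2 of the OLS fit on the given predictor subset, from moment matrices."""
    idx = list(subset)
    if not idx:
        return 0.0
    c_xx = cov_xx[np.ix_(idx, idx)]
    c_xy = cov_xy[idx]
    try:
        beta = np.linalg.solve(c_xx, c_xy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(c_xx, c_xy, rcond=None)[0]
    return float(c_xy @ beta / var_y)


def dominance_analysis(
    y: np.ndarray, X: np.ndarray, names: list[str] | None = None
) -> DominanceResult:
    """Exhaustive general-dominance decomposition of y ~ X."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{i + 1}" for i in range(p)]
    if len(names) != p:
        raise DataError("names length must match number of predictors")
    if p > MAX_PREDICTORS:
        raise DataError(f"p={p} exceeds the exhaustive-enumeration limit {MAX_PREDICTORS}")
    if y.shape != (n,):
        raise DataError("y must be a vector matching X rows")
    if n <= p + 1:
        raise InsufficientDataError(f"need n > p + 1, got n={n}, p={p}")
    if np.ptp(y) == 0:
        raise DataError("y is constant")
    col_sd = X.std(axis=0)
    if np.any(col_sd == 0):
        bad = [names[i] for i in np.flatnonzero(col_sd == 0)]
        raise CollinearityError(f"constant predictors: {bad}", columns=bad)

    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    cov_xx = Xc.T @ Xc
    cov_xy = Xc.T @ yc
    var_y = float(yc @ yc)

    rank = np.linalg.matrix_rank(Xc)
    if rank < p:
        # name columns nearly perfectly predicted by the others
        bad = []
        for i in range(p):
            others = [j for j in range(p) if j != i]
            r2 = _subset_r2(cov_xx, Xc.T @ Xc[:, i], float(Xc[:, i] @ Xc[:, i]), others)
            if r2 > 1 - 1e-10:
                bad.append(names[i])
        raise CollinearityError(
            f"rank-deficient full model; dependent columns: {bad or names}",
            columns=bad or names,
        )

    r2_cache: dict[int, float] = {0: 0.0}

    def r2_of(bitmask: int, members: tuple[int, ...]) -> float:
        if bitmask not in r2_cache:
            r2_cache[bitmask] = _subset_r2(cov_xx, cov_xy, var_y, members)
        return r2_cache[bitmask]

    general = np.zeros(p)
    others_all = list(range(p))
    for i in range(p):
        others = [j for j in others_all if j != i]
        size_means = []
        for s in range(p):
            incs = []
            for subset in combinations(others, s):
                base_mask = sum(1 << j for j in subset)
                with_i = base_mask | (1 << i)
                incs.append(
                    r2_of(with_i, tuple(sorted(subset + (i,))))
                    - r2_of(base_mask, subset)
                )
            size_means.append(float(np.mean(incs)))
        general[i] = float(np.mean(size_means))

    total_r2 = r2_of((1 << p) - 1, tuple(range(p)))
    percentage = 100.0 * general / total_r2 if total_r2 > 0 else np.full(p, np.nan)
    return DominanceResult(
        predictors=tuple(names),
        general_dominance=general,
        percentage=percentage,
        total_r2=total_r2,
        n_models=2**p - 1,
    )


def landscape_dominance(
    tau: ScalarMap,
    alff: ScalarMap,
    fcd_local: ScalarMap,
    fcd_long_range: ScalarMap,
    fcd_global: ScalarMap,
    min_voxels: int = 100,
) -> DominanceResult:
    """Dominance of [local FCD, long-range FCD, global FCD, ALFF] for the timescale map.

    Voxels missing in any map are dropped listwise; all variables are
    z-scored across the remaining voxels (percentages are scale-invariant,
    standardization just conditions the moment matrices).
    """
    maps = {
        "local_fcd": fcd_local,
        "long_range_fcd": fcd_long_range,
        "global_fcd": fcd_global,
        "alff": alff,
    }
    for name, m in maps.items():
        if m.mask is not tau.mask and m.mask.n_voxels != tau.mask.n_voxels:
            raise DataError(f"map {name} does not share the timescale mask")
    stack = np.column_stack([m.values for m in maps.values()])
    ok = ~np.isnan(tau.values) & ~np.isnan(stack).any(axis=1)
    if ok.sum() < min_voxels:
        raise InsufficientDataError(
            f"only {int(ok.sum())} shared voxels (< {min_voxels})"
        )
    y = tau.values[ok]
    X = stack[ok]
    y = (y - y.mean()) / y.std(ddof=1)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return dominance_analysis(y, X, names=list(maps.keys()))
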