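"""Parcel-level spatial association between a difference map and annotation
(receptor/transporter density) maps.

The target map is aggregated to atlas parcels, and for each annotation map a
partial Spearman correlation is computed, adjusting both rank vectors for a
gray-matter-probability confound profile.  Significance comes from
permutation of the target's parcel assignment; family-wise error across the
annotation family uses the single-step max-|rho| distribution from the same
permutations.  The parcel-exchangeability null ignores residual spatial
autocorrelation between parcels (documented limitation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DataError, DegenerateSignalError, InsufficientDataError
from .io_core import Parcellation, ScalarMap

log = logging.getLogger("neurotau")

MIN_VOXELS_PER_PARCEL = 5
MIN_SHARED_PARCELS = 10


@dataclass
class ParcelProfile:
    """One value per parcel; NaN marks parcels flagged missing."""

    parcel_ids: np.ndarray
    values: np.ndarray
    source_name: str = ""

    def __post_init__(self):
        self.parcel_ids = np.asarray(self.parcel_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.parcel_ids.shape != self.values.shape:
            raise DataError("parcel_ids and values must align")

    def series(self) -> pd.Series:
        return pd.Series(self.values, index=self.parcel_ids, name=self.source_name)


@dataclass(frozen=True)
class SpatialAssocResult:
    map_names: tuple[str, ...]
    rho: np.ndarray
    p_perm: np.ndarray
    p_fwe: np.ndarray
    n_parcels_used: int
    n_permutations: int
    seed: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "map": self.map_names,
                "rho": self.rho,
                "p_perm": self.p_perm,
                "p_fwe": self.p_fwe,
                "n_parcels": self.n_parcels_used,
            }
        )


def parcel_aggregate(
    scalar_map: ScalarMap,
    parc: Parcellation,
    min_voxels: int = MIN_VOXELS_PER_PARCEL,
) -> ParcelProfile:
    """Mean of non-missing in-mask voxel values per parcel.

    Parcels with fewer than ``min_voxels`` contributing voxels are flagged
    missing.
    """
    if not parc.grid.matches(scalar_map.mask.grid):
        raise DataError("parcellation and map do not share a grid")
    labels = parc.labels.ravel(order="C")[scalar_map.mask.flat_indices]
    vals = scalar_map.values
    ids = parc.parcel_ids
    out = np.full(ids.size, np.nan)
    for i, pid in enumerate(ids):
        v = vals[labels == pid]
        v = v[~np.isnan(v)]
        if v.size >= min_voxels:
            out[i] = v.mean()
    if np.isnan(out).all():
        raise InsufficientDataError("no parcel has enough contributing voxels")
    return ParcelProfile(parcel_ids=ids, values=out, source_name=scalar_map.name)


def _rank_z(v: np.ndarray) -> np.ndarray:
    r = rankdata(v, method="average")
    if np.ptp(r) == 0:
        raise DegenerateSignalError("profile is constant after ranking")
    return r


def _residualize(v: np.ndarray, confound: np.ndarray) -> np.ndarray:
    """Residual of v on [1, confound]."""
    Z = np.column_stack([np.ones_like(confound), confound])
    beta = np.linalg.lstsq(Z, v, rcond=None)[0]
    return v - Z @ beta


def partial_spearman(x, y, z) -> float:
    """Spearman correlation of x and y after regressing z out of both rank vectors."""
    x, y, z = (np.asarray(np.asarray(a, dtype=float)) for a in (x, y, z))
    ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(z))
    if ok.sum() < MIN_SHARED_PARCELS:
        raise InsufficientDataError(
            f"only {int(ok.sum())} shared parcels (< {MIN_SHARED_PARCELS})"
        )
    rx, ry = _rank_z(x[ok]), _rank_z(y[ok])
    rz = rankdata(z[ok], method="average")
    ex = _residualize(rx, rz)
    ey = _residualize(ry, rz)
    nx, ny = np.linalg.norm(ex), np.linalg.norm(ey)
    # residual indistinguishable from rounding noise -> partial rho undefined
    floor = 1e-8 * np.linalg.norm(rx - rx.mean())
    if nx <= floor or ny <= floor:
        raise DegenerateSignalError("profile fully explained by the confound")
    return float(ex @ ey / (nx * ny))


def _aligned_values(profiles: list[ParcelProfile]) -> np.ndarray:
    ids0 = profiles[0].parcel_ids
    for p in profiles[1:]:
        if p.parcel_ids.shape != ids0.shape or not np.array_equal(p.parcel_ids, ids0):
            raise DataError("profiles are not defined over the same parcels")
    return np.vstack([p.values for p in profiles])


def annotation_association(
    target: ParcelProfile,
    annotations: list[ParcelProfile],
    gm: ParcelProfile,
    n_perm: int = 5000,
    seed: int = 0,
) -> SpatialAssocResult:
    """Partial Spearman of the target with each annotation, permutation p and
    single-step max-|rho| FWE across the annotation family."""
    if len(annotations) < 1:
        raise DataError("need at least one annotation map")
    stack = _aligned_values([target, gm] + annotations)
    ok = ~np.isnan(stack).any(axis=0)
    n_used = int(ok.sum())
    if n_used < MIN_SHARED_PARCELS:
        raise InsufficientDataError(f"only {n_used} shared parcels")
    tgt = stack[0, ok]
    gmv = stack[1, ok]
    annot = stack[2:, ok]

    rz = rankdata(gmv, method="average")
    rt = _rank_z(tgt)
    e_annot = []
    for a in annot:
        ea = _residualize(_rank_z(a), rz)
        na = np.linalg.norm(ea)
        if na == 0:
            raise DegenerateSignalError("annotation fully explained by the confound")
        e_annot.append(ea / na)
    e_annot = np.vstack(e_annot)

    def _rho_vector(t_ranks: np.ndarray) -> np.ndarray:
        et = _residualize(t_ranks, rz)
        nt = np.linalg.norm(et)
        if nt == 0:
            raise DegenerateSignalError("target fully explained by the confound")
        return e_annot @ (et / nt)

    rho_obs = _rho_vector(rt)

    rng = np.random.default_rng(seed)
    log.info("annotation_association: n_perm=%d seed=%d", n_perm, seed)
    count = np.zeros(len(annotations), dtype=int)
    count_max = np.zeros(len(annotations), dtype=int)
    for _ in range(n_perm):
        rho_star = _rho_vector(rt[rng.permutation(n_used)])
        abs_star = np.abs(rho_star)
        count += abs_star >= np.abs(rho_obs) - 1e-12
        count_max += abs_star.max() >= np.abs(rho_obs) - 1e-12
    p_perm = (1 + count) / (n_perm + 1)
    p_fwe = (1 + count_max) / (n_perm + 1)
    return SpatialAssocResult(
        map_names=tuple(a.source_name or f"annotation_{i}" for i, a in enumerate(annotations)),
        rho=rho_obs,
        p_perm=p_perm,
        p_fwe=np.maximum(p_fwe, p_perm),
        n_parcels_used=n_used,
        n_permutations=n_perm,
        seed=seed,
    )


def atlas_robustness(
    scalar_map: ScalarMap,
    parcellations: list[Parcellation],
    annotations_per_parc: list[list[ParcelProfile]],
    gm_per_parc: list[ParcelProfile],
    n_perm: int = 5000,
    seed: int = 0,
) -> tuple[list[SpatialAssocResult], pd.DataFrame]:
    """Rerun the association under several atlases and report sign agreement."""
    if not (len(parcellations) == len(annotations_per_parc) == len(gm_per_parc)):
        raise DataError("per-parcellation inputs must align")
    results = []
    for i, parc in enumerate(parcellations):
        target = parcel_aggregate(scalar_map, parc)
        results.append(
            annotation_association(
                target, annotations_per_parc[i], gm_per_parc[i],
                n_perm=n_perm, seed=seed + i,
            )
        )
    names = results[0].map_names
    for r in results[1:]:
        if r.map_names != names:
            raise DataError("annotation families differ across parcellations")
    signs = np.vstack([np.sign(r.rho) for r in results])
    agreement = pd.DataFrame(
        {
            "map": names,
            "sign_agreement": (np.abs(signs.sum(axis=0)) == len(results)),
        }
    )
    return results, agreement
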