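"""Synthetic resting-state cohort with known ground truth.

The generator emulates the statistical structure the analysis assumes,
without any attempt at scanner physics:

* voxel-wise AR(1) BOLD signals whose coefficient phi follows a smooth
  spatial gradient (posterior-to-anterior axis), so the intrinsic timescale
  landscape has a known closed form tau = TR * phi / (1 - phi);
* a patient group whose phi is reduced by ``delta_phi`` inside planted
  effect regions, with the reduction shrinking multiplicatively across
  illness-duration stages (defaults 1.0 / 0.4 / 0.0) to emulate an effect
  that fades as illness duration grows;
* a block parcellation with left/right hemisphere tags;
* annotation (receptor/transporter stand-in) parcel profiles with planted
  partial Spearman correlation to the parcel-level true difference map,
  given a gray-matter confound profile;
* a gene x parcel expression matrix with a planted subset of genes
  correlated (positively or negatively) with the true difference profile,
  and a GMT collection whose "PLANTED" term contains the planted genes.

All randomness flows from one config seed, expanded into per-subject and
per-stage substreams via seed sequences, so generation is bit-reproducible
and independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigError
from .io_core import BoldRun, Mask, Parcellation, ScalarMap, SubjectTable, VolumeGrid
from .spatial_assoc import ParcelProfile, parcel_aggregate

DEFAULT_ANNOTATION_RHOS = {
    "5HT2a": 0.7,
    "D1": 0.6,
    "D2": 0.5,
    "DAT": 0.6,
    "FDOPA": 0.5,
    "NAT": 0.5,
    "SERT": 0.6,
    "GABAa": 0.0,
    "5HT1a": 0.0,
    "5HT1b": 0.0,
}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic cohort."""

    shape: tuple[int, int, int] = (10, 10, 10)
    mask_fraction: float = 1.0
    n_hc: int = 20
    n_mdd_per_stage: tuple[int, int, int] = (20, 10, 10)
    n_timepoints: int = 300
    tr_seconds: float = 2.0
    burn_in: int = 200
    phi_range: tuple[float, float] = (0.2, 0.7)
    effect_regions: tuple = (((2, 7), (2, 7), (5, 9)),)
    delta_phi: float = 0.25
    stage_multipliers: tuple[float, float, float] = (1.0, 0.4, 0.0)
    noise_sd: float = 1.0
    noise_smooth_sigma: float = 0.6
    n_parcels: int = 125
    annotation_rhos: dict = field(default_factory=lambda: dict(DEFAULT_ANNOTATION_RHOS))
    gm_loading: float = 0.3
    n_genes: int = 1500
    n_planted_genes: int = 60
    planted_gene_r: float = 0.9
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.phi_range
        if not (0 < lo < hi < 1):
            raise ConfigError(f"need 0 < phi_low < phi_high < 1, got {self.phi_range}")
        if self.delta_phi < 0:
            raise ConfigError("delta_phi must be >= 0")
        mults = self.stage_multipliers
        if any(mults[i] < mults[i + 1] for i in range(len(mults) - 1)):
            raise ConfigError(f"stage multipliers must be non-increasing: {mults}")
        if self.n_planted_genes > self.n_genes:
            raise ConfigError("n_planted_genes > n_genes")
        for rho in self.annotation_rhos.values():
            if abs(rho) >= 1:
                raise ConfigError(f"annotation rho must satisfy |rho| < 1, got {rho}")
        if not 0 < self.mask_fraction <= 1:
            raise ConfigError("mask_fraction must be in (0, 1]")
        if self.n_timepoints < 20:
            raise ConfigError("need at least 20 timepoints")


@dataclass
class SynthTruth:
    """Ground truth of a generated cohort."""

    config: SynthConfig
    mask: Mask
    phi_map: np.ndarray  # per in-mask voxel (healthy baseline)
    true_tau_map: ScalarMap  # TR * phi / (1 - phi)
    effect_mask: np.ndarray  # bool per in-mask voxel
    subject_stage: np.ndarray  # 0 for HC, 1..3 for patients
    subject_delta: np.ndarray  # phi reduction actually applied per subject
    parcellation: Parcellation
    diff_profile: ParcelProfile  # parcel-level true tau difference (MDD - HC, stage-1 delta)
    annotation_rhos: dict
    planted_genes: dict  # gene symbol -> +1 / -1 (sign of planted correlation)


# ---------------------------------------------------------------------------
# Geometry helpers


def _make_mask(config: SynthConfig) -> Mask:
    shape = config.shape
    grid = VolumeGrid(shape=shape, affine=np.diag([2.0, 2.0, 2.0, 1.0]))
    if config.mask_fraction >= 1.0:
        indicator = np.ones(shape, dtype=bool)
    else:
        # keep the mask_fraction of voxels nearest the volume center
        coords = np.indices(shape).reshape(3, -1).T.astype(float)
        center = (np.asarray(shape) - 1) / 2.0
        dist = np.linalg.norm(coords - center, axis=1)
        n_keep = max(1, int(round(config.mask_fraction * coords.shape[0])))
        order = np.argsort(dist, kind="stable")
        indicator = np.zeros(int(np.prod(shape)), dtype=bool)
        indicator[order[:n_keep]] = True
        indicator = indicator.reshape(shape)
    return Mask(grid=grid, indicator=indicator)


def _phi_map(config: SynthConfig, mask: Mask) -> np.ndarray:
    """Smooth spatial gradient of AR(1) coefficients over in-mask voxels."""
    lo, hi = config.phi_range
    coords = mask.voxel_coords.astype(float)
    nx, ny, nz = config.shape
    grad = coords[:, 2] / max(nz - 1, 1)
    phi = lo + (hi - lo) * grad
    # mild transverse modulation so parcel profiles are not exactly tied
    phi = phi + 0.02 * np.sin(2 * np.pi * coords[:, 0] / nx) + 0.02 * np.sin(
        2 * np.pi * coords[:, 1] / ny
    )
    return np.clip(phi, 0.02, 0.97)


def _effect_mask(config: SynthConfig, mask: Mask) -> np.ndarray:
    coords = mask.voxel_coords
    eff = np.zeros(mask.n_voxels, dtype=bool)
    for (x0, x1), (y0, y1), (z0, z1) in config.effect_regions:
        inside = (
            (coords[:, 0] >= x0)
            & (coords[:, 0] < x1)
            & (coords[:, 1] >= y0)
            & (coords[:, 1] < y1)
            & (coords[:, 2] >= z0)
            & (coords[:, 2] < z1)
        )
        eff |= inside
    return eff


def block_parcellation(mask: Mask, n_parcels: int, offset: int = 0) -> Parcellation:
    """Deterministic block atlas; hemisphere tags from the parcel centroid.

    Axes are split into near-equal runs of voxels; the actual parcel count is
    the product of per-axis splits nearest ``n_parcels``.  ``offset`` shifts
    the block boundaries, giving an alternative atlas over the same grid.
    """
    shape = mask.grid.shape
    per_axis = max(1, int(round(n_parcels ** (1 / 3))))
    splits = [min(per_axis, s) for s in shape]
    edges = []
    for axis, n_blocks in enumerate(splits):
        idx = (np.arange(shape[axis]) + offset) % shape[axis]
        # boundaries of np.array_split over the axis length
        block_of = np.concatenate(
            [np.full(len(chunk), b) for b, chunk in enumerate(np.array_split(idx, n_blocks))]
        )
        # map voxel coordinate -> block id through the shifted ordering
        coord_block = np.empty(shape[axis], dtype=int)
        coord_block[idx] = block_of
        edges.append(coord_block)
    bx, by, bz = np.meshgrid(edges[0], edges[1], edges[2], indexing="ij")
    labels = (bx * splits[1] * splits[2] + by * splits[2] + bz + 1).astype(np.int32)
    labels = np.where(mask.indicator, labels, 0)

    hemisphere = {}
    mid = (shape[0] - 1) / 2.0
    for pid in np.unique(labels[labels > 0]):
        xs = np.argwhere(labels == pid)[:, 0]
        cx = xs.mean()
        if cx < mid - 1e-9:
            hemisphere[int(pid)] = "left"
        elif cx > mid + 1e-9:
            hemisphere[int(pid)] = "right"
        else:
            hemisphere[int(pid)] = "midline"
    return Parcellation(grid=mask.grid, labels=labels, hemisphere=hemisphere)


def _true_tau(phi: np.ndarray, tr: float) -> np.ndarray:
    return tr * phi / (1.0 - phi)


# ---------------------------------------------------------------------------
# Cohort generation


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _smooth_factor(shape: tuple[int, int, int], sigma: float) -> float:
    """1/||kernel||_2 for periodic Gaussian smoothing (variance renormalization)."""
    from scipy.ndimage import gaussian_filter

    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    k = gaussian_filter(impulse, sigma=sigma, mode="wrap")
    return float(1.0 / np.sqrt((k**2).sum()))


def _simulate_ar1(
    phi: np.ndarray,
    T: int,
    burn_in: int,
    noise_sd: float,
    rng: np.random.Generator,
    mask: Mask | None = None,
    smooth_sigma: float = 0.0,
) -> np.ndarray:
    """Voxel-wise AR(1) signals x_t = phi x_{t-1} + eps_t.

    With ``smooth_sigma`` > 0 the innovations are spatially smoothed
    (periodic Gaussian kernel, variance renormalized), which induces
    realistic spatial correlation between voxels without changing any
    voxel's marginal AR(1) law or its autocorrelation function.
    """
    from scipy.ndimage import gaussian_filter

    n = phi.size
    x = np.zeros(n)
    out = np.empty((n, T))
    if smooth_sigma > 0 and mask is not None:
        shape = mask.grid.shape
        factor = _smooth_factor(shape, smooth_sigma)
        full = rng.normal(scale=noise_sd, size=(burn_in + T, *shape))
        full = gaussian_filter(full, sigma=(0, *(smooth_sigma,) * 3), mode="wrap")
        eps = factor * full.reshape(burn_in + T, -1)[:, mask.flat_indices]
    else:
        eps = rng.normal(scale=noise_sd, size=(burn_in + T, n))
    for t in range(burn_in):
        x = phi * x + eps[t]
    for t in range(T):
        x = phi * x + eps[burn_in + t]
        out[:, t] = x
    return out


def generate_cohort(config: SynthConfig) -> tuple[list[BoldRun], SubjectTable, SynthTruth]:
    """Generate BOLD runs, the subject table and the ground truth."""
    mask = _make_mask(config)
    phi = _phi_map(config, mask)
    eff = _effect_mask(config, mask)
    if np.any(phi[eff] - config.delta_phi <= 0):
        raise ConfigError("phi - delta_phi must stay positive inside effect regions")

    n_mdd = sum(config.n_mdd_per_stage)
    n_total = config.n_hc + n_mdd
    stages = np.concatenate(
        [
            np.zeros(config.n_hc, dtype=int),
            np.concatenate(
                [np.full(k, s + 1, dtype=int) for s, k in enumerate(config.n_mdd_per_stage)]
            )
            if n_mdd
            else np.zeros(0, dtype=int),
        ]
    )

    # covariates from a dedicated substream (index n_total keeps it disjoint
    # from the per-subject signal streams)
    rng_cov = _subject_rng(config.seed, n_total)
    age = np.clip(np.round(rng_cov.normal(35, 8, n_total)), 18, 60)
    sex = np.where(rng_cov.random(n_total) < 0.5, "F", "M")
    mean_fd = np.abs(rng_cov.normal(0.10, 0.04, n_total)) + 0.02
    snr0 = rng_cov.normal(100, 10, n_total)
    education = np.clip(np.round(rng_cov.normal(12, 3, n_total)), 6, 20)
    duration = np.full(n_total, np.nan)
    hamd = np.full(n_total, np.nan)
    stage_bounds = {1: (0.5, 12.0), 2: (12.5, 24.0), 3: (24.5, 96.0)}
    for i in range(n_total):
        if stages[i] > 0:
            lo, hi = stage_bounds[int(stages[i])]
            duration[i] = np.round(rng_cov.uniform(lo, hi), 1)
            hamd[i] = rng_cov.integers(17, 29)

    subject_ids = [
        (f"hc{i + 1:03d}" if stages[i] == 0 else f"mdd{i - config.n_hc + 1:03d}")
        for i in range(n_total)
    ]
    table = SubjectTable(
        pd.DataFrame(
            {
                "subject_id": subject_ids,
                "group": np.where(stages == 0, "HC", "MDD"),
                "age": age,
                "sex": sex,
                "mean_fd": mean_fd,
                "snr0": snr0,
                "education": education,
                "illness_duration": duration,
                "hamd": hamd,
            }
        )
    )

    mults = np.array([0.0, *config.stage_multipliers])
    subject_delta = config.delta_phi * mults[stages]
    runs = []
    for i in range(n_total):
        phi_i = phi.copy()
        if subject_delta[i] > 0:
            phi_i[eff] = phi_i[eff] - subject_delta[i]
        rng = _subject_rng(config.seed, i)
        data = _simulate_ar1(
            phi_i,
            config.n_timepoints,
            config.burn_in,
            config.noise_sd,
            rng,
            mask=mask,
            smooth_sigma=config.noise_smooth_sigma,
        )
        runs.append(
            BoldRun(
                subject_id=subject_ids[i],
                data=data,
                tr_seconds=config.tr_seconds,
                mask=mask,
            )
        )

    parc = block_parcellation(mask, config.n_parcels)
    tau_hc = _true_tau(phi, config.tr_seconds)
    tau_map = ScalarMap(values=tau_hc, mask=mask, name="true_tau", units="s")
    tau_mdd = tau_hc.copy()
    tau_mdd[eff] = _true_tau(phi[eff] - config.delta_phi, config.tr_seconds)
    diff_map = ScalarMap(
        values=tau_mdd - tau_hc, mask=mask, name="true_tau_diff", units="s"
    )
    diff_profile = parcel_aggregate(diff_map, parc, min_voxels=1)

    # planted genes: a seeded choice of symbols, alternating correlation sign
    rng_gene = _subject_rng(config.seed, n_total + 1)
    gene_names = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    planted_idx = rng_gene.choice(config.n_genes, config.n_planted_genes, replace=False)
    planted = {
        gene_names[g]: (1 if j % 2 == 0 else -1)
        for j, g in enumerate(sorted(planted_idx))
    }

    truth = SynthTruth(
        config=config,
        mask=mask,
        phi_map=phi,
        true_tau_map=tau_map,
        effect_mask=eff,
        subject_stage=stages,
        subject_delta=subject_delta,
        parcellation=parc,
        diff_profile=diff_profile,
        annotation_rhos=dict(config.annotation_rhos),
        planted_genes=planted,
    )
    return runs, table, truth


# ---------------------------------------------------------------------------
# Annotation maps


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def generate_annotations(
    truth: SynthTruth, config: SynthConfig | None = None
) -> tuple[dict[str, ParcelProfile], ParcelProfile]:
    """Annotation profiles with planted partial Spearman correlation to the
    true difference profile, plus the gray-matter confound profile.

    Planting operates on rank-standardized, confound-residualized profiles:
    y = rho * u + sqrt(1 - rho^2) * e + gm_loading * g, where u is the
    standardized rank-residual of the target given gm and e an independent
    standardized residual, so the planted rho is a partial Spearman by
    construction (up to the final ranking of y).
    """
    config = config or truth.config
    rng = _subject_rng(config.seed, 900_001)
    target = truth.diff_profile.values
    ok = ~np.isnan(target)
    n = int(ok.sum())

    gm_raw = rng.normal(size=n)
    gm = 0.5 + 0.1 * _standardize(gm_raw)
    gm_ranks = rankdata(gm, method="average")

    t_ranks = rankdata(target[ok], method="average")
    Z = np.column_stack([np.ones(n), gm_ranks])

    def _resid_std(v):
        r = v - Z @ np.linalg.lstsq(Z, v, rcond=None)[0]
        return r / np.linalg.norm(r)

    u = _resid_std(t_ranks)
    g_std = _standardize(gm_ranks)

    profiles = {}
    for name, rho in truth.annotation_rhos.items():
        noise = rng.normal(size=n)
        e = _resid_std(rankdata(noise, method="average"))
        y = rho * u + np.sqrt(1 - rho**2) * e
        y = _standardize(y) + config.gm_loading * g_std
        vals = np.full(target.size, np.nan)
        vals[ok] = y
        profiles[name] = ParcelProfile(
            parcel_ids=truth.diff_profile.parcel_ids, values=vals, source_name=name
        )
    gm_vals = np.full(target.size, np.nan)
    gm_vals[ok] = gm
    gm_profile = ParcelProfile(
        parcel_ids=truth.diff_profile.parcel_ids, values=gm_vals, source_name="gm_probability"
    )
    return profiles, gm_profile


# ---------------------------------------------------------------------------
# Expression matrix and gene sets


def generate_expression(truth: SynthTruth, config: SynthConfig | None = None):
    """Gene x parcel expression with planted spatially-correlated genes and a
    GMT collection containing a PLANTED term plus random decoy terms."""
    from .transcriptome import ExpressionMatrix, GeneSetCollection

    config = config or truth.config
    rng = _subject_rng(config.seed, 900_002)
    target = truth.diff_profile.values
    ok = ~np.isnan(target)
    n = int(ok.sum())
    ids = truth.diff_profile.parcel_ids[ok]

    std_diff = _standardize(target[ok])
    # a shared smooth spatial component (the phi gradient aggregated to
    # parcels) gives null genes realistic spatial structure
    grad_profile = parcel_aggregate(truth.true_tau_map, truth.parcellation, min_voxels=1)
    grad = _standardize(grad_profile.values[ok])

    gene_names = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    r = config.planted_gene_r
    E = np.empty((config.n_genes, n))
    for i, name in enumerate(gene_names):
        noise = rng.normal(size=n)
        if name in truth.planted_genes:
            sign = truth.planted_genes[name]
            E[i] = sign * (r * std_diff + np.sqrt(1 - r**2) * _standardize(noise))
        else:
            E[i] = 0.3 * grad + np.sqrt(1 - 0.09) * _standardize(noise)

    hemi = pd.Series(
        {int(pid): truth.parcellation.hemisphere[int(pid)] for pid in ids}
    )
    expr = ExpressionMatrix(
        values=pd.DataFrame(E, index=gene_names, columns=[int(p) for p in ids]),
        hemisphere=hemi,
    )

    planted_set = set(truth.planted_genes)
    decoys = [g for g in gene_names if g not in planted_set]
    rng_sets = _subject_rng(config.seed, 900_003)
    terms, descriptions = {}, {}
    if planted_set:
        n_decoys = min(len(planted_set) // 2, len(decoys))
        terms["PLANTED"] = frozenset(
            list(planted_set)
            + list(rng_sets.choice(decoys, size=n_decoys, replace=False))
        )
        descriptions["PLANTED"] = "planted spatially correlated genes plus decoys"
    lo = max(5, config.n_genes // 30)
    hi = max(lo + 1, config.n_genes // 8)
    for j in range(19):
        size = int(rng_sets.integers(lo, hi + 1))
        terms[f"RANDOM{j + 1:02d}"] = frozenset(
            rng_sets.choice(gene_names, size=size, replace=False)
        )
        descriptions[f"RANDOM{j + 1:02d}"] = "random decoy set"
    return expr, GeneSetCollection(terms=terms, descriptions=descriptions)
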