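import numpy as np
import pytest
from scipy.stats import rankdata, spearmanr

from neurotau.errors import DataError, InsufficientDataError
from neurotau.io_core import Parcellation, ScalarMap
from neurotau.spatial_assoc import (
    ParcelProfile,
    annotation_association,
    atlas_robustness,
    parcel_aggregate,
    partial_spearman,
)
from neurotau.synth import block_parcellation
from tests.conftest import make_mask


def brute_force_partial_spearman(x, y, z):
    """Explicit rank vectors + two small regressions."""
    rx, ry, rz = (rankdata(v) for v in (x, y, z))
    Z = np.column_stack([np.ones_like(rz), rz])
    bx = np.linalg.solve(Z.T @ Z, Z.T @ rx)
    by = np.linalg.solve(Z.T @ Z, Z.T @ ry)
    ex, ey = rx - Z @ bx, ry - Z @ by
    return float(ex @ ey / np.sqrt((ex @ ex) * (ey @ ey)))


def _profiles(n=60, seed=0):
    rng = np.random.default_rng(seed)
    ids = np.arange(1, n + 1)

    def mk(v, name=""):
        return ParcelProfile(parcel_ids=ids, values=v, source_name=name)

    return rng, ids, mk


class TestParcelAggregate:
    def _setup(self):
        mask = make_mask((4, 4, 2))
        labels = np.zeros((4, 4, 2), dtype=np.int32)
        labels[:2] = 1
        labels[2:] = 2
        parc = Parcellation(grid=mask.grid, labels=labels,
                            hemisphere={1: "left", 2: "right"})
        return mask, parc

    def test_constant_map(self):
        mask, parc = self._setup()
        prof = parcel_aggregate(
            ScalarMap(values=np.full(32, 3.5), mask=mask, name="c"), parc
        )
        np.testing.assert_allclose(prof.values, [3.5, 3.5])

    def test_hand_mean(self):
        mask, parc = self._setup()
        vals = np.ones(32)
        # parcel 1 occupies the first 16 in-mask voxels (row-major)
        vals[:8] = 1.0
        vals[8:16] = 3.0
        prof = parcel_aggregate(ScalarMap(values=vals, mask=mask, name="m"), parc)
        assert prof.values[0] == pytest.approx(2.0)

    def test_small_parcel_flagged_missing(self):
        mask, parc = self._setup()
        vals = np.random.default_rng(0).normal(size=32)
        vals[:14] = np.nan  # parcel 1 has only 2 contributing voxels
        prof = parcel_aggregate(ScalarMap(values=vals, mask=mask, name="m"), parc)
        assert np.isnan(prof.values[0])
        assert np.isfinite(prof.values[1])


class TestPartialSpearman:
    def test_constant_confound_equals_spearman(self):
        rng, ids, mk = _profiles()
        x = rng.normal(size=60)
        y = 0.5 * x + rng.normal(size=60)
        z = np.zeros(60) + rng.normal() * 0  # constant
        rho = partial_spearman(x, y, z)
        assert rho == pytest.approx(spearmanr(x, y).statistic, abs=1e-10)

    def test_confound_nearly_identical_to_y_gives_near_zero(self):
        # residual orthogonality: adjusting y for itself leaves no signal
        rng, ids, mk = _profiles(seed=1)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        z = y + 1e-3 * rng.normal(size=200)  # y up to measurement noise
        assert abs(partial_spearman(x, y, z)) < 0.1

    def test_confound_exactly_y_is_degenerate(self):
        from neurotau.errors import DegenerateSignalError

        rng, ids, mk = _profiles(seed=1)
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        with pytest.raises(DegenerateSignalError):
            partial_spearman(x, y, y)

    def test_monotone_invariance(self):
        rng, ids, mk = _profiles(seed=2)
        latent = rng.normal(size=60)
        x = np.exp(latent)
        y = latent**3
        z = rng.normal(size=60)
        assert partial_spearman(x, y, z) > 0.95

    def test_matches_brute_force_oracle(self):
        rng, ids, mk = _profiles(seed=3)
        for _ in range(10):
            x, y, z = rng.normal(size=(3, 40))
            assert partial_spearman(x, y, z) == pytest.approx(
                brute_force_partial_spearman(x, y, z), abs=1e-10
            )

    def test_too_few_parcels_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(InsufficientDataError):
            partial_spearman(rng.normal(size=5), rng.normal(size=5),
                             rng.normal(size=5))


class TestAnnotationAssociation:
    def test_identity_annotation_minimal_p(self):
        rng, ids, mk = _profiles(n=80, seed=5)
        target = mk(rng.normal(size=80), "target")
        gm = mk(rng.normal(size=80), "gm")
        annotations = [
            ParcelProfile(parcel_ids=ids, values=target.values.copy(),
                          source_name="same"),
            mk(rng.normal(size=80), "noise"),
        ]
        res = annotation_association(target, annotations, gm, n_perm=199, seed=0)
        i = res.map_names.index("same")
        assert res.rho[i] == pytest.approx(1.0, abs=1e-10)
        assert res.p_fwe[i] == pytest.approx(1 / 200)
        assert res.p_fwe[i] >= res.p_perm[i]

    def test_planted_partial_rho_recovered(self):
        # y = rho z* + sqrt(1-rho^2) eps on standardized rank residuals
        rho_true = 0.6
        rng = np.random.default_rng(6)
        n = 200
        ids = np.arange(1, n + 1)
        estimates = []
        for _ in range(10):
            gm = rng.normal(size=n)
            target = rng.normal(size=n)
            rz = rankdata(gm)
            Z = np.column_stack([np.ones(n), rz])

            def resid_std(v):
                r = v - Z @ np.linalg.lstsq(Z, v, rcond=None)[0]
                return r / np.linalg.norm(r)

            u = resid_std(rankdata(target))
            e = resid_std(rankdata(rng.normal(size=n)))
            y = rho_true * u + np.sqrt(1 - rho_true**2) * e
            estimates.append(partial_spearman(target, y, gm))
        estimates = np.asarray(estimates)
        # central tendency recovers the planted value; single replicates vary
        # with the estimator's sampling noise (sd ~ (1-rho^2)/sqrt(n))
        assert abs(estimates.mean() - rho_true) < 0.12
        assert np.all(np.abs(estimates - rho_true) < 0.2)

    def test_monotone_transform_invariance(self):
        rng, ids, mk = _profiles(n=100, seed=7)
        base = rng.normal(size=100)
        target = mk(base, "t")
        target_t = mk(np.exp(base), "t")
        annot = [mk(0.7 * base + rng.normal(size=100), "a")]
        gm = mk(rng.normal(size=100), "gm")
        r1 = annotation_association(target, annot, gm, n_perm=99, seed=1)
        r2 = annotation_association(target_t, annot, gm, n_perm=99, seed=1)
        assert r1.rho[0] == pytest.approx(r2.rho[0], abs=1e-12)
        assert r1.p_perm[0] == r2.p_perm[0]

    def test_mismatched_parcels_rejected(self):
        rng, ids, mk = _profiles(seed=8)
        target = mk(rng.normal(size=60))
        gm = mk(rng.normal(size=60))
        other = ParcelProfile(parcel_ids=np.arange(2, 62),
                              values=rng.normal(size=60), source_name="x")
        with pytest.raises(DataError):
            annotation_association(target, [other], gm, n_perm=99, seed=0)


class TestAtlasRobustness:
    def test_sign_agreement_across_atlases(self):
        rng = np.random.default_rng(9)
        mask = make_mask((8, 8, 8))
        signal = rng.normal(size=mask.n_voxels)
        # spatially smooth the voxel signal so both atlases see it
        from scipy.ndimage import gaussian_filter

        vol = gaussian_filter(signal.reshape(8, 8, 8), 1.5).ravel()
        smap = ScalarMap(values=vol, mask=mask, name="t")
        parcs = [block_parcellation(mask, 64, offset=0),
                 block_parcellation(mask, 64, offset=1)]
        annots, gms = [], []
        for parc in parcs:
            target = parcel_aggregate(smap, parc)
            n = target.values.size
            planted = ParcelProfile(
                parcel_ids=target.parcel_ids,
                values=0.9 * target.values + 0.1 * rng.normal(size=n),
                source_name="planted",
            )
            noise = ParcelProfile(parcel_ids=target.parcel_ids,
                                  values=rng.normal(size=n), source_name="noise")
            annots.append([planted, noise])
            gms.append(ParcelProfile(parcel_ids=target.parcel_ids,
                                     values=rng.uniform(0.3, 0.9, n),
                                     source_name="gm"))
        results, agreement = atlas_robustness(smap, parcs, annots, gms,
                                              n_perm=99, seed=0)
        assert len(results) == 2
        planted_row = agreement[agreement["map"] == "planted"]
        assert bool(planted_row["sign_agreement"].iloc[0])
        for r in results:
            assert r.rho[r.map_names.index("planted")] > 0.5
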