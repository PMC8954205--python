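"""Phantom generator: atlas geometry, class effects, degradation model."""

import numpy as np
import pytest

from limbicnet.phantoms import (REGION_VALUES, CohortSpec, ScannerProfile,
                                build_atlas, degrade, generate_cohort,
                                make_phantom)
from limbicnet.volume import Volume

REQUIRED_REGIONS = ["cortex", "middle_frontal", "middle_temporal", "insula",
                    "hippocampus", "amygdala", "thalamus", "putamen", "caudate"]


class TestBuildAtlas:
    def test_every_required_region_present_and_sized(self, atlas64):
        for name in REQUIRED_REGIONS:
            voxels = atlas64.mask(name).sum()
            assert voxels >= 8, name

    def test_regions_pairwise_disjoint(self, atlas64):
        # one label per voxel by construction; verify labels partition masks
        total = sum((atlas64.labels == lab).sum()
                    for lab in atlas64.region_names)
        assert total == atlas64.brain_mask.sum()

    def test_bilateral_regions_left_right_symmetric(self, atlas64):
        r = atlas64.mask("hippocampus_r") if "hippocampus_r" in atlas64.names \
            else None
        left = np.isin(atlas64.labels, atlas64.labels_for("hippocampus")[0:1])
        right = np.isin(atlas64.labels, atlas64.labels_for("hippocampus")[1:2])
        assert left.sum() == right.sum()
        # mirrored voxel counts per x-slab
        lx = left.sum(axis=(1, 2))
        rx = right.sum(axis=(1, 2))
        assert np.array_equal(lx, rx[::-1])

    def test_region_centroids_inside_brain(self, atlas64):
        for name in REQUIRED_REGIONS:
            m = atlas64.mask(name)
            centroid = np.round(np.mean(np.argwhere(m), axis=0)).astype(int)
            assert atlas64.brain_mask[tuple(centroid)], name

    def test_background_is_zero_outside_brain(self, atlas64):
        assert (atlas64.labels[~atlas64.brain_mask] == 0).all()

    def test_minimum_dims_still_fit_every_region(self):
        atlas = build_atlas((16, 16, 16))
        for name in REQUIRED_REGIONS:
            assert atlas.mask(name).sum() >= 1, name

    def test_dims_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            build_atlas((8, 8, 8))


class TestMakePhantom:
    def test_control_unaffected_by_effect_map(self, atlas32, rng):
        vol = make_phantom(atlas32, "control", {"hippocampus": 0.3}, rng,
                           subject_sd=0.0)
        hip = atlas32.mask("hippocampus")
        assert vol.data[hip].mean() == pytest.approx(
            REGION_VALUES["hippocampus"], rel=1e-6)

    def test_ad_effect_recovered_in_sample_mean(self, atlas32):
        """Monte-Carlo: mean AD hippocampus intensity ~ 0.7x baseline
        within 3 standard errors over 100 subjects."""
        rng = np.random.default_rng(7)
        sd = 0.05
        vals = []
        for _ in range(100):
            vol = make_phantom(atlas32, "ad", {"hippocampus": 0.3}, rng,
                               subject_sd=sd)
            vals.append(vol.data[atlas32.mask("hippocampus")].mean())
        vals = np.array(vals)
        expected = 0.7 * REGION_VALUES["hippocampus"]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expected) < 3 * se + 1e-3 * expected

    def test_empty_effect_map_gives_identical_distributions(self, atlas32):
        rng_a = np.random.default_rng(5)
        rng_b = np.random.default_rng(5)
        ctrl = make_phantom(atlas32, "control", {}, rng_a)
        ad = make_phantom(atlas32, "ad", {}, rng_b)
        np.testing.assert_array_equal(ctrl.data, ad.data)

    def test_background_is_zero(self, atlas32, rng):
        vol = make_phantom(atlas32, "control", {}, rng)
        assert (vol.data[~atlas32.brain_mask] == 0).all()

    def test_unknown_effect_region_rejected(self, atlas32, rng):
        with pytest.raises(KeyError):
            make_phantom(atlas32, "ad", {"cerebellum": 0.2}, rng)


class TestDegrade:
    def test_identity_degradation(self, atlas32, rng):
        clean = make_phantom(atlas32, "control", {}, rng)
        out = degrade(clean, ScannerProfile("id", 0.0, 0.0,
                                            clean.n_slices), rng)
        np.testing.assert_array_equal(out.data, clean.data)

    def test_blur_preserves_slice_mass(self, atlas32, rng):
        """Normalized-kernel convolution conserves per-slice activity up to
        boundary handling."""
        clean = make_phantom(atlas32, "control", {}, rng)
        out = degrade(clean, ScannerProfile("b", 2.0, 0.0,
                                            clean.n_slices), rng)
        for z in range(clean.n_slices):
            s_in = clean.data[:, :, z].sum()
            if s_in > 0:
                # mirror boundary handling near the field-of-view edge moves
                # a little mass; a few percent is the expected scale
                assert out.data[:, :, z].sum() == pytest.approx(s_in, rel=0.03)

    def test_noise_sd_scales_with_mean_intensity(self, atlas32):
        """Monte-Carlo: sd of (out - in) over in-brain voxels ~ noise_sd x
        mean intensity within 5%."""
        rng = np.random.default_rng(11)
        clean = make_phantom(atlas32, "control", {}, rng, subject_sd=0.0)
        brain = clean.data > 0
        mean_int = clean.data[brain].mean()
        out = degrade(clean, ScannerProfile("n", 0.0, 0.1, clean.n_slices),
                      rng)
        # clipping at zero does not affect in-brain voxels (values >> noise)
        resid = (out.data - clean.data)[brain]
        assert resid.std() == pytest.approx(0.1 * mean_int, rel=0.05)

    def test_slice_decimation(self, atlas32, rng):
        clean = make_phantom(atlas32, "control", {}, rng)
        out = degrade(clean, ScannerProfile("thin", 0.0, 0.0, 10), rng)
        assert out.n_slices == 10

    def test_degradation_composes_in_distribution(self, atlas32):
        """First two moments of blur-then-noise match the one-shot
        degradation over Monte-Carlo replicates."""
        rng = np.random.default_rng(3)
        clean = make_phantom(atlas32, "control", {}, rng, subject_sd=0.0)
        brain = clean.data > 0
        n = clean.n_slices
        one, two = [], []
        for i in range(10):
            r1 = np.random.default_rng(100 + i)
            r2 = np.random.default_rng(200 + i)
            d_one = degrade(clean, ScannerProfile("a", 1.5, 0.08, n), r1)
            blurred = degrade(clean, ScannerProfile("b", 1.5, 0.0, n), r2)
            d_two = degrade(Volume(blurred.data, clean.voxel_size),
                            ScannerProfile("c", 0.0, 0.08 * clean.data[brain].mean()
                                           / blurred.data[blurred.data > 0].mean(),
                                           n), r2)
            one.append(d_one.data[brain])
            two.append(d_two.data[brain])
        one = np.concatenate(one)
        two = np.concatenate(two)
        assert one.mean() == pytest.approx(two.mean(), rel=0.01)
        assert one.std() == pytest.approx(two.std(), rel=0.05)


class TestGenerateCohort:
    def _spec(self, tmp, seed=0):
        scan = ScannerProfile("s", 1.0, 0.05, 16)
        return CohortSpec(n_control=4, n_ad=2, dims=(32, 32, 20),
                          effect_map={"hippocampus": 0.3},
                          scanner_profiles=((scan, 1.0),), seed=seed)

    def test_manifest_counts(self, tmp_path):
        manifest = generate_cohort(self._spec(tmp_path), tmp_path)
        assert len(manifest) == 6
        assert (manifest["label"] == "control").sum() == 4

    def test_seeded_determinism_bitwise(self, tmp_path):
        m1 = generate_cohort(self._spec(tmp_path), tmp_path / "a")
        m2 = generate_cohort(self._spec(tmp_path), tmp_path / "b")
        assert m1.equals(m2)
        for rel in m1["volume"]:
            assert (tmp_path / "a" / rel).read_bytes() == \
                (tmp_path / "b" / rel).read_bytes()
        assert (tmp_path / "a" / "manifest.tsv").read_bytes() == \
            (tmp_path / "b" / "manifest.tsv").read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        generate_cohort(self._spec(tmp_path, seed=0), tmp_path / "a")
        generate_cohort(self._spec(tmp_path, seed=1), tmp_path / "b")
        va = Volume.from_nifti(tmp_path / "a" / "sub-0000.nii.gz")
        vb = Volume.from_nifti(tmp_path / "b" / "sub-0000.nii.gz")
        assert (va.data != vb.data).any()

    def test_roundtrip_through_nifti(self, tmp_path):
        generate_cohort(self._spec(tmp_path), tmp_path)
        vol = Volume.from_nifti(tmp_path / "sub-0000.nii.gz")
        assert vol.dims == (32, 32, 16)
        assert (vol.data >= 0).all()
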