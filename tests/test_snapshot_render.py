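import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snapqsar import conformer3d as c3
from snapqsar import snapshot_render as sr


@pytest.fixture(scope="module")
def asym_conformer():
    # bromo-ether: clearly asymmetric under rotation
    return c3.smiles_to_conformer("CCOc1ccc(Br)cc1", embed_seed=1,
                                  compound_id="asym")


class TestEnumerateViewpoints:
    @pytest.mark.parametrize("theta,count", [
        (195, 8), (185, 8), (176, 27), (165, 27), (155, 27), (145, 27),
        (100, 64), (95, 64), (340, 8), (350, 8),
    ])
    def test_published_angle_count_pairs(self, theta, count):
        assert len(sr.enumerate_viewpoints((theta,) * 3)) == count

    def test_360_gives_identity_only(self):
        vps = sr.enumerate_viewpoints((360, 360, 360))
        assert vps == [sr.Viewpoint(0, 0, 0)]

    def test_nonpositive_theta_rejected(self):
        with pytest.raises(ValueError):
            sr.enumerate_viewpoints((0, 195, 195))
        with pytest.raises(ValueError):
            sr.SnapshotSpec(theta=(-10, 195, 195))

    def test_lexicographic_order_and_multiples(self):
        vps = sr.enumerate_viewpoints((195, 176, 340))
        assert len(vps) == 2 * 3 * 2
        assert vps[0] == sr.Viewpoint(0, 0, 0)
        for vp in vps:
            for comp, theta in zip((vp.rx, vp.ry, vp.rz), (195, 176, 340)):
                k = comp / theta
                assert abs(k - round(k)) < 1e-12
                assert 0 <= comp < 360

    # lower bound 36 keeps the product of per-axis counts <= 1000
    @given(theta=st.tuples(*[st.floats(36.0, 360.0)] * 3))
    @settings(max_examples=200)
    def test_count_law_against_bruteforce(self, theta):
        vps = sr.enumerate_viewpoints(theta)
        expected = 1
        for t in theta:
            k, n = 0, 0
            while k * t < 360.0:  # brute-force multiple counting
                n += 1
                k += 1
            expected *= n
        assert len(vps) == expected


class TestRotateConformer:
    def test_identity_viewpoint(self, asym_conformer):
        rotated = sr.rotate_conformer(asym_conformer, sr.Viewpoint(0, 0, 0))
        assert np.allclose(rotated.coords, asym_conformer.coords, atol=1e-12)

    def test_two_quarter_turns_equal_half_turn(self, asym_conformer):
        once = sr.rotate_conformer(asym_conformer, sr.Viewpoint(90, 0, 0))
        twice = sr.rotate_conformer(once, sr.Viewpoint(90, 0, 0))
        direct = sr.rotate_conformer(asym_conformer, sr.Viewpoint(180, 0, 0))
        assert np.allclose(twice.coords, direct.coords, atol=1e-9)

    def test_matrix_product_oracle(self):
        # composed rotation equals the product of the generating matrices
        vp = sr.Viewpoint(33, 121, 287)
        m = sr.rotation_matrix(vp)
        mx = sr.rotation_matrix(sr.Viewpoint(33, 0, 0))
        my = sr.rotation_matrix(sr.Viewpoint(0, 121, 0))
        mz = sr.rotation_matrix(sr.Viewpoint(0, 0, 287))
        assert np.allclose(m, mz @ my @ mx, atol=1e-12)

    def test_centroid_preserved(self, asym_conformer):
        rotated = sr.rotate_conformer(asym_conformer, sr.Viewpoint(195, 195, 0))
        assert np.allclose(rotated.coords.mean(axis=0),
                           asym_conformer.coords.mean(axis=0), atol=1e-9)

    def test_distances_preserved(self, asym_conformer):
        rotated = sr.rotate_conformer(asym_conformer, sr.Viewpoint(45, 195, 340))
        def pdist(c):
            d = c[:, None, :] - c[None, :, :]
            return np.sqrt((d ** 2).sum(-1))
        assert np.allclose(pdist(rotated.coords),
                           pdist(asym_conformer.coords), atol=1e-9)


class TestBackgroundColors:
    @pytest.mark.parametrize("name,rgb", [
        ("aquamarine", (0.5, 1.0, 1.0)),
        ("blue-white", (0.85, 0.85, 1.00)),
        ("Grey70", (0.7, 0.7, 0.7)),
        ("Grey80", (0.8, 0.8, 0.8)),
        ("Grey90", (0.9, 0.9, 0.9)),
        ("light blue", (0.75, 0.75, 1.00)),
        ("light pink", (1.00, 0.75, 0.87)),
        ("pale cyan", (0.8, 1.0, 1.0)),
        ("pale green", (0.65, 0.90, 0.65)),
        ("pale yellow", (1.0, 1.0, 0.5)),
        ("violet", (1.0, 0.5, 1.0)),
        ("bright orange", (1.0, 0.7, 0.2)),
        ("deep salmon", (1.0, 0.5, 0.5)),
        ("gold", (1.00, 0.82, 0.14)),
        ("light orange", (1.0, 0.8, 0.5)),
        ("salmon", (1.0, 0.6, 0.6)),
        ("tv_orange", (1.00, 0.55, 0.15)),
        ("yellow-orange", (1.00, 0.87, 0.37)),
        ("black", (0.0, 0.0, 0.0)),
    ])
    def test_extended_palette(self, name, rgb):
        assert sr.resolve_background_color(name) == rgb

    @pytest.mark.parametrize("name", ["blue", "cyan", "green", "magenta",
                                      "orange", "red", "wheat", "white",
                                      "yellow"])
    def test_primary_names_resolve(self, name):
        rgb = sr.resolve_background_color(name)
        assert len(rgb) == 3
        assert all(0.0 <= v <= 1.0 for v in rgb)

    def test_explicit_triple_passthrough(self):
        assert sr.resolve_background_color((0.2, 0.3, 0.4)) == (0.2, 0.3, 0.4)

    def test_unknown_name_lists_valid(self):
        with pytest.raises(KeyError, match="aquamarine"):
            sr.resolve_background_color("no-such-color")

    def test_out_of_range_triple(self):
        with pytest.raises(ValueError):
            sr.resolve_background_color((1.2, 0.0, 0.0))


class TestRenderSnapshot:
    def test_shape_and_dtype(self, asym_conformer):
        img = sr.render_snapshot(asym_conformer, sr.Viewpoint(0, 0, 0),
                                 sr.SnapshotSpec())
        assert img.shape == (256, 256, 3)
        assert img.dtype == np.uint8

    def test_corner_pixels_equal_background(self, asym_conformer):
        spec = sr.SnapshotSpec(background="wheat")
        img = sr.render_snapshot(asym_conformer, sr.Viewpoint(195, 0, 195), spec)
        expected = np.array([round(v * 255) for v in
                             sr.resolve_background_color("wheat")])
        for corner in (img[0, 0], img[0, -1], img[-1, 0], img[-1, -1]):
            assert np.array_equal(corner, expected)

    def test_pixel_identical_rerenders(self, asym_conformer):
        spec = sr.SnapshotSpec()
        a = sr.render_snapshot(asym_conformer, sr.Viewpoint(195, 195, 0), spec)
        b = sr.render_snapshot(asym_conformer, sr.Viewpoint(195, 195, 0), spec)
        assert np.array_equal(a, b)

    def test_viewpoint_sensitivity(self, asym_conformer):
        spec = sr.SnapshotSpec()
        a = sr.render_snapshot(asym_conformer, sr.Viewpoint(0, 0, 0), spec)
        b = sr.render_snapshot(asym_conformer, sr.Viewpoint(195, 195, 195), spec)
        assert not np.array_equal(a, b)

    def test_molecule_drawn_not_just_background(self, asym_conformer):
        spec = sr.SnapshotSpec()
        img = sr.render_snapshot(asym_conformer, sr.Viewpoint(0, 0, 0), spec)
        assert (img != 255).any()

    def test_background_change_leaves_molecule_pixels(self, asym_conformer):
        vp = sr.Viewpoint(0, 0, 0)
        white = sr.render_snapshot(asym_conformer, vp,
                                   sr.SnapshotSpec(background="white"))
        black = sr.render_snapshot(asym_conformer, vp,
                                   sr.SnapshotSpec(background="black"))
        changed = np.any(white != black, axis=2)
        was_bg = np.all(white == 255, axis=2)
        # only pixels that showed the old background may change
        assert np.all(was_bg[changed])

    def test_small_image_size_rejected(self):
        with pytest.raises(ValueError):
            sr.SnapshotSpec(image_size=16)


class TestGenerateSnapshots:
    def test_count_one_molecule_theta195(self, tmp_path, asym_conformer):
        spec = sr.SnapshotSpec(theta=(195, 195, 195), image_size=64)
        manifest = sr.generate_snapshots([asym_conformer], spec, tmp_path)
        assert len(manifest) == 8
        assert len(list(tmp_path.glob("*.png"))) == 8

    def test_count_two_molecules_theta176(self, tmp_path):
        confs = [c3.smiles_to_conformer(s, compound_id=f"m{i}")
                 for i, s in enumerate(("CC", "CCO"))]
        spec = sr.SnapshotSpec(theta=(176, 176, 176), image_size=32)
        manifest = sr.generate_snapshots(confs, spec, tmp_path)
        assert len(manifest) == 54
        assert len(list(tmp_path.glob("*.png"))) == 54

    def test_empty_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            sr.generate_snapshots([], sr.SnapshotSpec(), tmp_path)

    def test_idempotent_rerun_skips_existing(self, tmp_path, asym_conformer):
        spec = sr.SnapshotSpec(theta=(360, 360, 360), image_size=32)
        sr.generate_snapshots([asym_conformer], spec, tmp_path,
                              overwrite=False)
        png = next(tmp_path.glob("*.png"))
        mtime = png.stat().st_mtime_ns
        sr.generate_snapshots([asym_conformer], spec, tmp_path,
                              overwrite=False)
        assert png.stat().st_mtime_ns == mtime

    def test_manifest_columns(self, tmp_path, asym_conformer):
        spec = sr.SnapshotSpec(theta=(360, 360, 360), image_size=32)
        manifest = sr.generate_snapshots(
            [asym_conformer], spec, tmp_path,
            molecule_info={"asym": {"split": "train", "label": 1}})
        row = manifest.iloc[0]
        assert row["split"] == "train"
        assert row["label"] == 1
        assert row["compound_id"] == "asym"
        assert (row["rx"], row["ry"], row["rz"]) == (0, 0, 0)
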