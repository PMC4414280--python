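"""Band-collapse protocol, generalized Procrustes, vector assembly."""

import dataclasses

import numpy as np
import pytest

import wingquant as wq
from wingquant.landmarks import (
    LM1,
    LM7,
    LM14,
    LandmarkSet,
    band_slice,
    collapse_bands,
    procrustes_align,
)


def make_intersections(outline, present, truncate=None):
    """Synthetic band/vein intersections: band b at x=10*(b+1), veins at y=0..5."""
    inters, extents = [], []
    for b in range(6):
        if not present[b]:
            inters.append(None)
            extents.append((0, 5))
            continue
        pts = np.column_stack((np.full(6, 10.0 * (b + 1)), np.arange(6, dtype=float)))
        first, last = (0, 5) if truncate is None or b not in truncate else truncate[b]
        full = np.full((6, 2), np.nan)
        full[first : last + 1] = pts[first : last + 1]
        inters.append(full)
        extents.append((first, last))
    return inters, extents


class TestCollapse:
    def test_all_present_identity(self, outline):
        inters, ext = make_intersections(outline, [True] * 6)
        out = collapse_bands(inters, [True] * 6, ext, outline)
        for b in range(6):
            assert np.allclose(out.band_points(b), inters[b])
        assert np.allclose(out.outline, outline)
        assert not out.collapse_flags

    def test_missing_band_I_collapses_to_apex(self, outline):
        """No band exists apically of band I, so its points go to LM 7."""
        present = [False, True, True, True, True, True]
        inters, ext = make_intersections(outline, present)
        out = collapse_bands(inters, present, ext, outline)
        assert np.allclose(out.band_points(0), np.tile(outline[LM7], (6, 1)))

    def test_missing_band_II_takes_band_I(self, outline):
        present = [True, False, True, True, True, True]
        inters, ext = make_intersections(outline, present)
        out = collapse_bands(inters, present, ext, outline)
        assert np.allclose(out.band_points(1), out.band_points(0))

    def test_missing_band_VI_splits_between_LM1_and_LM14(self, outline):
        present = [True, True, True, True, True, False]
        inters, ext = make_intersections(outline, present)
        out = collapse_bands(inters, present, ext, outline)
        pts = out.band_points(5)
        assert np.allclose(pts[:3], np.tile(outline[LM1], (3, 1)))
        assert np.allclose(pts[3:], np.tile(outline[LM14], (3, 1)))

    def test_missing_band_IV_takes_basal_neighbour(self, outline):
        present = [True, True, True, False, True, True]
        inters, ext = make_intersections(outline, present)
        out = collapse_bands(inters, present, ext, outline)
        assert np.allclose(out.band_points(3), out.band_points(4))

    def test_truncated_band_collapses_medially(self, outline):
        """Edge points of a band not reaching the wing edges move to the
        nearest covered reference-vein intersection."""
        present = [True] * 6
        inters, ext = make_intersections(outline, present, truncate={2: (1, 4)})
        out = collapse_bands(inters, present, ext, outline)
        pts = out.band_points(2)
        assert np.allclose(pts[0], pts[1])  # anterior edge -> vein 1
        assert np.allclose(pts[5], pts[4])  # posterior edge -> vein 4
        assert "truncated" in out.collapse_flags[2]

    def test_fully_bandless_wing_is_legal(self, outline):
        out = collapse_bands([None] * 6, [False] * 6, None, outline)
        for b in (0, 1, 2):
            assert np.allclose(out.band_points(b), np.tile(outline[LM7], (6, 1)))
        for b in (3, 4, 5):
            pts = out.band_points(b)
            assert np.allclose(pts[:3], outline[LM1])
            assert np.allclose(pts[3:], outline[LM14])

    def test_idempotence(self, outline):
        present = [False, True, False, True, False, False]
        inters, ext = make_intersections(outline, present)
        once = collapse_bands(inters, present, ext, outline)
        again_in = [once.band_points(b) if present[b] else None for b in range(6)]
        twice = collapse_bands(again_in, present, ext, outline)
        assert np.allclose(once.coords, twice.coords)

    def test_never_invents_coordinates(self, outline):
        present = [True, False, False, False, True, False]
        inters, ext = make_intersections(outline, present, truncate={0: (2, 5)})
        out = collapse_bands(inters, present, ext, outline)
        allowed = np.vstack(
            [outline[[LM1, LM7, LM14]]]
            + [p[~np.isnan(p[:, 0])] for p in inters if p is not None]
        )
        for pt in out.coords[14:]:
            assert np.min(np.abs(allowed - pt).sum(axis=1)) < 1e-12

    def test_malformed_intersections_rejected(self, outline):
        inters, ext = make_intersections(outline, [True] * 6)
        inters[2] = inters[2][:4]  # wrong shape
        with pytest.raises(ValueError):
            collapse_bands(inters, [True] * 6, ext, outline)
        with pytest.raises(ValueError):
            collapse_bands([None] * 5, [False] * 5, None, outline)


def random_shape(rng, n=50):
    return LandmarkSet(coords=rng.normal(size=(n, 2)) * 10 + 5)


class TestProcrustes:
    def test_similarity_transform_removed(self):
        rng = np.random.default_rng(0)
        a = random_shape(rng)
        th = np.radians(30)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        b = LandmarkSet(coords=(a.coords @ rot.T) * 2.0 + np.array([13.0, -4.0]))
        aligned = procrustes_align([a, b])
        d = np.sqrt(((aligned[0].coords - aligned[1].coords) ** 2).sum())
        assert d < 1e-9

    def test_matches_closed_form_two_shape_opa(self):
        """Pairwise distance after GPA equals ordinary Procrustes analysis."""
        rng = np.random.default_rng(1)
        a, b = random_shape(rng), random_shape(rng)
        aligned = procrustes_align([a, b])
        d_gpa = np.sqrt(((aligned[0].coords - aligned[1].coords) ** 2).sum())
        # independent closed-form OPA: center, unit-scale, optimal rotation
        X = a.coords - a.coords.mean(0)
        Y = b.coords - b.coords.mean(0)
        X /= np.sqrt((X**2).sum())
        Y /= np.sqrt((Y**2).sum())
        u, s, vt = np.linalg.svd(X.T @ Y)
        if np.linalg.det(u @ vt) < 0:
            s = s.copy()
            s[-1] = -s[-1]
        d_opa = np.sqrt(max(0.0, 2.0 - 2.0 * s.sum()))
        assert d_gpa == pytest.approx(d_opa, abs=1e-6)

    def test_normalization_of_aligned_sets(self):
        rng = np.random.default_rng(2)
        aligned = procrustes_align([random_shape(rng) for _ in range(5)])
        for s in aligned:
            assert np.allclose(s.centroid(), 0.0, atol=1e-9)
            assert s.centroid_size() == pytest.approx(1.0, abs=1e-9)
            assert s.units == "procrustes"

    def test_objective_monotone_over_iterations(self):
        """Summed squared deviation from the consensus never increases."""
        from wingquant.landmarks import _normalize, _rotate_onto

        rng = np.random.default_rng(3)
        shapes = [_normalize(random_shape(rng).coords) for _ in range(6)]
        consensus = shapes[0].copy()
        prev = np.inf
        for _ in range(20):
            shapes = [_rotate_onto(sh, consensus) for sh in shapes]
            obj = sum(((sh - consensus) ** 2).sum() for sh in shapes)
            assert obj <= prev + 1e-12
            prev = obj
            consensus = _normalize(np.mean(shapes, axis=0))

    def test_degenerate_set_rejected(self):
        flat = LandmarkSet(coords=np.ones((50, 2)))
        with pytest.raises(ValueError):
            procrustes_align([flat, flat])

    def test_requires_two_sets(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            procrustes_align([random_shape(rng)])


class TestAssemble:
    def test_vector_length_and_order(self):
        rng = np.random.default_rng(5)
        f, h = random_shape(rng), random_shape(rng)
        h = LandmarkSet(coords=h.coords, wing="hind")
        fa, ha = procrustes_align([f, LandmarkSet(coords=f.coords + rng.normal(size=(50, 2)))])
        hb, _ = procrustes_align([h, LandmarkSet(coords=h.coords * 2, wing="hind")])
        v = wq.assemble_vector(fa, hb)
        assert v.values.shape == (200,)
        assert np.allclose(v.values[:100], fa.coords.ravel())
        assert np.allclose(v.values[100:], hb.coords.ravel())

    def test_rejects_unaligned(self):
        rng = np.random.default_rng(6)
        raw = random_shape(rng)
        with pytest.raises(ValueError):
            wq.assemble_vector(raw, raw)

    def test_zero_shapes_give_zero_vector(self):
        z = LandmarkSet(coords=np.zeros((50, 2)), units="procrustes")
        assert np.all(wq.assemble_vector(z, z).values == 0.0)

    def test_tps_round_trip_preserves_vector(self, tmp_path):
        rng = np.random.default_rng(7)
        fa, ha = procrustes_align([random_shape(rng), random_shape(rng)])
        path = tmp_path / "round.tps"
        wq.write_tps(
            [wq.TPSRecord(coords=fa.coords, id="f"), wq.TPSRecord(coords=ha.coords, id="h")],
            path,
        )
        back = {r.id: r.coords for r in wq.read_tps(path)}
        v1 = wq.assemble_vector(fa, ha).values
        fa2 = LandmarkSet(coords=back["f"], units="procrustes")
        ha2 = LandmarkSet(coords=back["h"], wing="hind", units="procrustes")
        v2 = wq.assemble_vector(fa2, ha2).values
        assert np.allclose(v1, v2, atol=1e-6)


class TestMeanShape:
    def test_single_and_pair_groups(self):
        rng = np.random.default_rng(8)
        aligned = procrustes_align([random_shape(rng) for _ in range(3)])
        means = wq.mean_shape(aligned, ["a", "b", "b"])
        assert np.allclose(means["a"].coords, aligned[0].coords)
        assert np.allclose(
            means["b"].coords, (aligned[1].coords + aligned[2].coords) / 2
        )

    def test_empty_label_mismatch(self):
        rng = np.random.default_rng(9)
        aligned = procrustes_align([random_shape(rng) for _ in range(2)])
        with pytest.raises(ValueError):
            wq.mean_shape(aligned, ["a"])

    def test_zero_jitter_mean_matches_forward_map(self, forms):
        """With no jitter, the per-form Procrustes mean equals any single
        specimen's normalized truth configuration."""
        spec = dataclasses.replace(forms["victoriaM"], jitter_sd=0.0, color_noise_sd=0.0)
        other = dataclasses.replace(forms["auroraM"], jitter_sd=0.0, color_noise_sd=0.0)
        sets, labels = [], []
        for i, (s, lab) in enumerate(
            [(spec, "vic")] * 3 + [(other, "aur")] * 3
        ):
            sp = wq.render_specimen(s, 256, seed=100 + i)
            sets.append(LandmarkSet(coords=sp.truth_fore_lms, wing="fore"))
            labels.append(lab)
        aligned = procrustes_align(sets, wing="fore")
        means = wq.mean_shape(aligned, labels)
        # forward map: normalize the known truth configuration and rotate onto
        # the group mean (both live in Procrustes space up to rotation)
        from wingquant.landmarks import _normalize, _rotate_onto

        truth = _normalize(sets[0].coords)
        mapped = _rotate_onto(truth, means["vic"].coords)
        assert np.allclose(mapped, means["vic"].coords, atol=1e-3)
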