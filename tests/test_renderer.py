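"""Compositing correctness: painter's rule, exactness, determinism."""

import numpy as np
import pytest

from conftest import render_masks, tile_of
from vlstitch.errors import LayoutError
from vlstitch.fragment_io import fragment_from_array, make_thumbnail, read_fragment
from vlstitch.layout import FragmentPose, StitchLayout, canvas_bounds, pose_to_matrix
from vlstitch.matting import AlphaMask, compute_alpha_mask
from vlstitch.renderer import RenderJob, render_preview, render_tile, render_vls
from vlstitch.synth import CutPlan, fragment_section


def brute_force_render(layout, fragments, canvas_w, canvas_h, masks=None,
                       interpolation="nearest"):
    """Independent per-pixel inverse-mapping oracle (no shared code with
    the tile renderer beyond the pose matrix definition)."""
    by_id = {f.fragment_id: f for f in fragments}
    out = np.full((canvas_h, canvas_w, 3), 255, dtype=np.uint8)
    for pose in sorted(layout.poses, key=lambda p: p.z_order):
        frag = by_id[pose.fragment_id]
        arr = frag.level_array(0)
        h, w = arr.shape[:2]
        inv = np.linalg.inv(pose_to_matrix(pose, w, h))
        mask = None if masks is None else masks.get(pose.fragment_id)
        for y in range(canvas_h):
            for x in range(canvas_w):
                sx, sy, _ = inv @ np.array([x + 0.5, y + 0.5, 1.0])
                ix, iy = int(np.floor(sx)), int(np.floor(sy))
                if not (0 <= ix < w and 0 <= iy < h):
                    continue
                if mask is not None and mask.values[
                    min(iy // mask.factor, mask.height - 1),
                    min(ix // mask.factor, mask.width - 1),
                ] != 255:
                    continue
                if interpolation == "nearest":
                    out[y, x] = arr[iy, ix]
                else:  # bilinear on pixel centers
                    fx, fy = sx - 0.5, sy - 0.5
                    x0, y0 = int(np.floor(fx)), int(np.floor(fy))
                    dx, dy = fx - x0, fy - y0
                    acc = np.zeros(3)
                    for (yy, xx, wgt) in [
                        (y0, x0, (1 - dx) * (1 - dy)),
                        (y0, x0 + 1, dx * (1 - dy)),
                        (y0 + 1, x0, (1 - dx) * dy),
                        (y0 + 1, x0 + 1, dx * dy),
                    ]:
                        yy = min(max(yy, 0), h - 1)
                        xx = min(max(xx, 0), w - 1)
                        acc += wgt * arr[yy, xx]
                    out[y, x] = np.clip(np.rint(acc), 0, 255)
    return out


@pytest.fixture
def small_section(rng):
    """A 96x64 textured section for brute-force comparisons."""
    img = np.full((64, 96, 3), 255, dtype=np.uint8)
    img[8:56, 10:86] = rng.integers(30, 220, (48, 76, 3), dtype=np.uint8)
    return img


class TestRenderTile:
    def test_identity_pose_matches_fragment(self, rng):
        arr = rng.integers(0, 256, (40, 60, 3), dtype=np.uint8)
        frag = fragment_from_array(arr, 1.0, "f0")
        layout = StitchLayout([FragmentPose("f0")], mpp=1.0)
        tile = render_tile(layout, [frag], 0, (0, 0, 60, 40))
        assert np.array_equal(tile.pixels, arr)

    def test_overlap_resolved_by_z_order(self, rng):
        a = np.full((20, 20, 3), 50, dtype=np.uint8)
        b = np.full((20, 20, 3), 200, dtype=np.uint8)
        frags = [fragment_from_array(a, 1.0, "lo"), fragment_from_array(b, 1.0, "hi")]
        layout = StitchLayout(
            [FragmentPose("lo", z_order=0), FragmentPose("hi", tx=10, z_order=1)],
            mpp=1.0,
        )
        tile = render_tile(layout, frags, 0, (0, 0, 30, 20))
        assert (tile.pixels[:, 10:20] == 200).all()  # overlap: higher z wins
        assert (tile.pixels[:, :10] == 50).all()

    def test_two_fragment_cut_reassembles_exactly(self, rng):
        img = rng.integers(0, 256, (512, 512, 3), dtype=np.uint8)
        left = fragment_from_array(img[:, :256], 1.0, "L")
        right = fragment_from_array(img[:, 256:], 1.0, "R")
        layout = StitchLayout(
            [FragmentPose("L", z_order=0), FragmentPose("R", tx=256, z_order=1)],
            mpp=1.0,
        )
        tile = render_tile(layout, [left, right], 0, (0, 0, 512, 512))
        assert np.array_equal(tile.pixels, img)

    def test_unresolved_fragment_raises(self):
        layout = StitchLayout([FragmentPose("ghost")], mpp=1.0)
        with pytest.raises(LayoutError):
            render_tile(layout, [], 0, (0, 0, 8, 8))


class TestOracleEquivalence:
    @pytest.mark.parametrize("rot,fh,fv,tx,ty", [
        (0, False, False, 3, 5),
        (90, False, False, 10, 0),
        (180, True, False, 7, 11),
        (270, False, True, 0, 9),
        (90, True, True, 15, 2),
    ])
    def test_restricted_pose_group_exact(self, small_section, rot, fh, fv, tx, ty):
        frag = fragment_from_array(small_section, 1.0, "f0")
        pose = FragmentPose("f0", rotation_deg=rot, flip_h=fh, flip_v=fv, tx=tx, ty=ty)
        layout = StitchLayout([pose], mpp=1.0)
        cw, ch, _ = canvas_bounds(layout, [frag])
        got = render_tile(layout, [frag], 0, (0, 0, cw, ch)).pixels
        expect = brute_force_render(layout, [frag], cw, ch)
        assert np.array_equal(got, expect)

    def test_free_angle_bilinear_within_one_level(self, small_section):
        frag = fragment_from_array(small_section, 1.0, "f0")
        pose = FragmentPose("f0", rotation_deg=17.3, tx=20, ty=12)
        layout = StitchLayout([pose], mpp=1.0)
        cw, ch, shift = canvas_bounds(layout, [frag])
        from vlstitch.layout import shift_layout

        shifted = shift_layout(layout, shift)
        got = render_tile(shifted, [frag], 0, (0, 0, cw, ch),
                          interpolation="bilinear").pixels
        expect = brute_force_render(shifted, [frag], cw, ch,
                                    interpolation="bilinear")
        assert np.abs(got.astype(int) - expect.astype(int)).max() <= 1

    def test_masked_compositing_matches_oracle(self, small_section, rng):
        frag = fragment_from_array(small_section, 1.0, "f0")
        mask_vals = (rng.random((32, 48)) > 0.3).astype(np.uint8) * 255
        masks = {"f0": AlphaMask(mask_vals, factor=2)}
        layout = StitchLayout([FragmentPose("f0", rotation_deg=180, tx=4, ty=6)],
                              mpp=1.0)
        got = render_tile(layout, [frag], 0, (0, 0, 104, 76), masks=masks).pixels
        expect = brute_force_render(layout, [frag], 104, 76, masks=masks)
        assert np.array_equal(got, expect)


class TestTilingInvariance:
    def test_tile_grid_equals_single_tile(self, section):
        _, img, ann, _ = section
        frags, layout = fragment_section(img, ann, CutPlan(n_fragments=3, seed=5))
        cw, ch, _ = canvas_bounds(layout, frags)
        whole = render_tile(layout, frags, 0, (0, 0, cw, ch)).pixels
        stitched = np.zeros_like(whole)
        ts = 256
        for y in range(0, ch, ts):
            for x in range(0, cw, ts):
                w, h = min(ts, cw - x), min(ts, ch - y)
                stitched[y:y+h, x:x+w] = render_tile(
                    layout, frags, 0, (x, y, w, h)
                ).pixels
        assert np.array_equal(whole, stitched)


class TestRenderVls:
    def test_full_job_round_trip_and_determinism(self, tmp_path, section):
        _, img, ann, _ = section
        frags, layout = fragment_section(img, ann, CutPlan(n_fragments=4, seed=11))
        outs = []
        for name in ("a.tiff", "b.tiff"):
            progress = []
            job = RenderJob(layout=layout, fragments=frags,
                            out_path=str(tmp_path / name),
                            progress_callback=progress.append)
            render_vls(job)
            assert job.status == "done" and job.progress == 1.0
            assert all(b >= a for a, b in zip(progress, progress[1:]))
            outs.append(read_fragment(str(tmp_path / name)).level_array(0))
        assert np.array_equal(outs[0], outs[1])  # identical across runs
        assert np.array_equal(outs[0], img)  # exact reconstruction

    def test_empty_layout_errors_without_file(self, tmp_path):
        job = RenderJob(layout=StitchLayout([], mpp=1.0), fragments=[],
                        out_path=str(tmp_path / "x.tiff"))
        with pytest.raises(LayoutError):
            render_vls(job)
        assert job.status == "failed"
        assert not (tmp_path / "x.tiff").exists()

    def test_mpp_propagates_to_output(self, tmp_path, section):
        _, img, ann, _ = section
        frags, layout = fragment_section(img, ann, CutPlan(n_fragments=2, seed=1))
        job = RenderJob(layout=layout, fragments=frags,
                        out_path=str(tmp_path / "v.tiff"))
        render_vls(job)
        assert read_fragment(str(tmp_path / "v.tiff")).mpp == pytest.approx(
            layout.mpp, rel=1e-6
        )


class TestMaskedReconstruction:
    def test_clean_cut_masked_render_is_exact_on_tissue(self, section):
        # cuts away from the bed edge: matting recovers every tissue pixel
        _, img, ann, _ = section
        frags, layout = fragment_section(
            img, ann, CutPlan(n_fragments=2, jitter_px=0, seed=7)
        )
        cw, ch, _ = canvas_bounds(layout, frags)
        masks = render_masks(frags, dilate_px=1)
        out = render_tile(layout, frags, 0, (0, 0, cw, ch), masks=masks).pixels
        fg = (img < 250).any(axis=-1)
        assert (out[fg] == img[fg]).all()

    def test_masked_render_recovers_nearly_all_foreground(self, section):
        _, img, ann, _ = section
        frags, layout = fragment_section(img, ann, CutPlan(n_fragments=8, seed=3))
        cw, ch, _ = canvas_bounds(layout, frags)
        masks = render_masks(frags, dilate_px=2)
        out = render_tile(layout, frags, 0, (0, 0, cw, ch), masks=masks).pixels
        fg = (img < 250).any(axis=-1)
        assert (out[fg] == img[fg]).all(axis=-1).mean() >= 0.999

    def test_foreground_conservation(self, section):
        # tissue painted on the VLS == sum of per-fragment tissue coverage
        # minus overlap, with coverage counted by an independent inverse-map
        _, img, ann, _ = section
        frags, layout = fragment_section(img, ann, CutPlan(n_fragments=3, seed=9))
        cw, ch, _ = canvas_bounds(layout, frags)
        masks = render_masks(frags, dilate_px=0)
        by_id = {f.fragment_id: f for f in frags}
        ys, xs = np.mgrid[0:ch, 0:cw]
        cover = np.zeros((ch, cw), dtype=int)
        per_frag_counts = []
        for pose in layout.poses:
            frag = by_id[pose.fragment_id]
            arr = frag.level_array(0)
            inv = np.linalg.inv(pose_to_matrix(pose, frag.width_l0, frag.height_l0))
            sx = inv[0, 0] * (xs + 0.5) + inv[0, 1] * (ys + 0.5) + inv[0, 2]
            sy = inv[1, 0] * (xs + 0.5) + inv[1, 1] * (ys + 0.5) + inv[1, 2]
            ix, iy = np.floor(sx).astype(int), np.floor(sy).astype(int)
            ok = (ix >= 0) & (ix < frag.width_l0) & (iy >= 0) & (iy < frag.height_l0)
            m = masks[pose.fragment_id]
            ixc, iyc = np.clip(ix, 0, frag.width_l0 - 1), np.clip(iy, 0, frag.height_l0 - 1)
            tissue = ok & (m.values[np.minimum(iyc // m.factor, m.height - 1),
                                    np.minimum(ixc // m.factor, m.width - 1)] == 255)
            # only count pixels that carry actual (non-white) stain
            tissue &= (arr[iyc, ixc] < 255).any(axis=-1)
            cover += tissue
            per_frag_counts.append(int(tissue.sum()))
        vls = render_tile(layout, frags, 0, (0, 0, cw, ch), masks=masks).pixels
        union = int((cover > 0).sum())
        overlap = sum(per_frag_counts) - union
        painted = (vls < 255).any(axis=-1)
        # conservation: rendered tissue = fragment tissue totals - overlap
        assert int(painted.sum()) == sum(per_frag_counts) - overlap
        assert np.array_equal(painted, cover > 0)


class TestPreview:
    def _thumb_and_mask(self, frag, factor=2):
        thumb = make_thumbnail(frag, factor)
        mask = compute_alpha_mask(thumb, factor=factor)
        return thumb, mask

    def test_single_fragment_preview_is_masked_thumbnail(self, section):
        _, img, ann, _ = section
        frag = fragment_from_array(img, ann.mpp, "f0")
        thumb, mask = self._thumb_and_mask(frag)
        layout = StitchLayout([FragmentPose("f0", thumbnail_factor=2)],
                              mpp=ann.mpp, thumbnail_factor=2)
        prev = render_preview(layout, {"f0": thumb}, {"f0": mask})
        inside = mask.values == 255
        assert np.array_equal(prev.pixels[..., 3][: thumb.height, : thumb.width],
                              mask.values)
        assert np.array_equal(
            prev.pixels[..., :3][: thumb.height, : thumb.width][inside],
            thumb.pixels[inside],
        )

    def test_transparent_masks_give_white_preview(self, rng):
        arr = rng.integers(0, 200, (32, 32, 3), dtype=np.uint8)
        frag = fragment_from_array(arr, 1.0, "f0")
        thumb = make_thumbnail(frag, 1)
        empty = AlphaMask(np.zeros((32, 32), np.uint8))
        layout = StitchLayout([FragmentPose("f0", thumbnail_factor=1)], mpp=1.0,
                              thumbnail_factor=1)
        prev = render_preview(layout, {"f0": thumb}, {"f0": empty})
        assert (prev.pixels[..., :3] == 255).all()
        assert (prev.pixels[..., 3] == 0).all()

    def test_preview_consistent_with_downsampled_render(self, section):
        _, img, ann, _ = section
        frags, layout = fragment_section(img, ann, CutPlan(n_fragments=3, seed=2))
        factor = 4
        thumbs, masks = {}, {}
        for f in frags:
            t = make_thumbnail(f, factor)
            thumbs[f.fragment_id] = t
            masks[f.fragment_id] = compute_alpha_mask(t, factor=factor)
        from dataclasses import replace

        small_layout = StitchLayout(
            [replace(p, thumbnail_factor=factor) for p in layout.poses],
            mpp=layout.mpp, thumbnail_factor=factor,
        )
        prev = render_preview(small_layout, thumbs, masks)
        cw, ch, _ = canvas_bounds(layout, frags)
        full = render_tile(layout, frags, 0, (0, 0, cw, ch)).pixels
        down = full[::factor, ::factor]
        fg = prev.pixels[..., 3] == 255
        hh = min(down.shape[0], prev.pixels.shape[0])
        ww = min(down.shape[1], prev.pixels.shape[1])
        diff = np.abs(
            prev.pixels[:hh, :ww, :3].astype(int) - down[:hh, :ww].astype(int)
        ).max(axis=-1)
        close = (diff <= 10) | ~fg[:hh, :ww]
        assert close.mean() >= 0.95

    def test_mismatched_mask_rejected(self, rng):
        arr = rng.integers(0, 200, (32, 32, 3), dtype=np.uint8)
        frag = fragment_from_array(arr, 1.0, "f0")
        thumb = make_thumbnail(frag, 1)
        bad = AlphaMask(np.zeros((16, 16), np.uint8))
        layout = StitchLayout([FragmentPose("f0", thumbnail_factor=1)], mpp=1.0)
        with pytest.raises(ValueError):
            render_preview(layout, {"f0": thumb}, {"f0": bad})
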