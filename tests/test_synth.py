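"""Tests for the synthetic tile / pseudo-WSI generators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ihcseg.ki67 import od_deconvolve
from ihcseg.synth import (CLASS_DCIS, CLASS_IC, NucleusClass, PseudoWSI,
                          Stain, TileSpec, WsiSpec, derive_boundary_gt,
                          generate_pseudo_wsi, generate_tile, read_ledger,
                          read_pseudo_wsi, read_tile_pair, write_ledger,
                          write_pseudo_wsi, write_tile)
from ihcseg.synth.tiles import NucleusTruth


class TestTileSpecValidation:
    def test_rejects_bad_size(self):
        with pytest.raises(ValueError):
            TileSpec(size_px=100)  # not divisible by 8
        with pytest.raises(ValueError):
            TileSpec(size_px=56)   # < 64

    def test_rejects_bad_positivity(self):
        with pytest.raises(ValueError):
            TileSpec(positivity=1.5)

    def test_rejects_bad_radius_ranges(self):
        with pytest.raises(ValueError):
            TileSpec(nest_size_range=(0, 10))
        with pytest.raises(ValueError):
            TileSpec(dcis_radius_range=(50, 20))

    def test_rejects_unknown_confounder(self):
        with pytest.raises(ValueError):
            TileSpec(confounders={"necrosis"})


class TestGenerateTile:
    def test_normal_scenario_mask_all_zero(self):
        tile = generate_tile(TileSpec(scenario="normal", seed=3))
        assert (tile.mask == 0).all()

    def test_seeded_determinism(self):
        a = generate_tile(TileSpec(scenario="dcis", seed=7))
        b = generate_tile(TileSpec(scenario="dcis", seed=7))
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_array_equal(a.boundary, b.boundary)

    @pytest.mark.parametrize("seed", range(8))
    def test_mixed_contains_both_classes_and_log_matches(self, seed):
        tile = generate_tile(TileSpec(scenario="mixed", seed=seed))
        assert (tile.mask == CLASS_DCIS).any()
        assert (tile.mask == CLASS_IC).any()
        for cls in (CLASS_DCIS, CLASS_IC):
            logged = sum(r.n_pixels for r in tile.placement_log
                         if r.nest_class == cls)
            assert logged == int((tile.mask == cls).sum())

    def test_scenario_purity(self):
        dcis = generate_tile(TileSpec(scenario="dcis", seed=1))
        assert (dcis.mask != CLASS_IC).all() and (dcis.mask == CLASS_DCIS).any()
        inv = generate_tile(TileSpec(scenario="invasive", seed=1))
        assert (inv.mask != CLASS_DCIS).all() and (inv.mask == CLASS_IC).any()

    def test_confounders_are_background(self):
        tile = generate_tile(TileSpec(scenario="normal", seed=5,
                                      confounders={"lobule", "lymphocytes"}))
        assert (tile.mask == 0).all()
        assert any(r.kind == "lymphocytes" for r in tile.placement_log)
        assert len(tile.nuclei) > 0

    def test_positive_nuclei_have_higher_dab_od(self):
        # label/appearance coupling, assertable on every tile
        tile = generate_tile(TileSpec(scenario="mixed", seed=2, positivity=0.5))
        dab = od_deconvolve(tile.image)["dab"]
        pos, neg = [], []
        for n in tile.nuclei:
            if n.nucleus_class in (NucleusClass.TUMOR_DCIS, NucleusClass.TUMOR_IC):
                (pos if n.marker_positive else neg).append(
                    dab[int(round(n.y)), int(round(n.x))])
        assert np.mean(pos) > np.mean(neg) + 0.5

    def test_her2_renders_membrane_chromogen(self):
        tile = generate_tile(TileSpec(scenario="invasive", seed=4,
                                      stain=Stain.HER2, positivity=1.0))
        dab = od_deconvolve(tile.image)["dab"]
        for n in tile.nuclei[:10]:
            if not n.marker_positive:
                continue
            r, c = int(round(n.y)), int(round(n.x))
            ring = dab[max(0, r - 5):r + 6, max(0, c - 5):c + 6].max()
            center = dab[r, c]
            assert ring > 0.5              # chromogen on the membrane ring
            assert center < ring           # not nuclear-filled


class TestBoundaryGT:
    def test_uniform_mask_no_boundary(self):
        assert derive_boundary_gt(np.ones((8, 8), dtype=np.uint8)).sum() == 0

    def test_half_split_width1_exactly_two_columns(self):
        # brute-force oracle: transitions live in columns 3 and 4 only
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[:, :4] = 1
        mask[:, 4:] = 2
        boundary = derive_boundary_gt(mask, width_px=1)
        expected = np.zeros((8, 8), dtype=np.uint8)
        expected[:, 3:5] = 1
        np.testing.assert_array_equal(boundary, expected)
        assert boundary.sum() == 16

    def test_matches_bruteforce_neighborhood_scan(self):
        rng = np.random.default_rng(0)
        mask = rng.integers(0, 3, (12, 12)).astype(np.uint8)
        for width in (1, 2, 3):
            got = derive_boundary_gt(mask, width)
            # independent oracle: direct double loop
            trans = np.zeros_like(mask, dtype=bool)
            h, w = mask.shape
            for r in range(h):
                for c in range(w):
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] != mask[r, c]:
                            trans[r, c] = True
            expected = np.zeros_like(mask, dtype=bool)
            ys, xs = np.nonzero(trans)
            for r in range(h):
                for c in range(w):
                    if any(max(abs(r - y), abs(c - x)) < width
                           for y, x in zip(ys, xs)):
                        expected[r, c] = True
            np.testing.assert_array_equal(got.astype(bool), expected)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_width_monotone(self, seed):
        mask = np.random.default_rng(seed).integers(0, 3, (16, 16)).astype(np.uint8)
        b1 = derive_boundary_gt(mask, 1)
        b2 = derive_boundary_gt(mask, 2)
        assert (b2 >= b1).all()

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            derive_boundary_gt(np.full((4, 4), 5))
        with pytest.raises(ValueError):
            derive_boundary_gt(np.zeros((4, 4), dtype=np.uint8), width_px=0)


class TestPseudoWSI:
    def test_rejects_too_small(self):
        with pytest.raises(ValueError):
            WsiSpec(width=600, height=600, context_side=512)

    def test_ledger_index_definition(self):
        nuclei = (
            [NucleusTruth(0, 0, NucleusClass.TUMOR_IC, True)] * 80
            + [NucleusTruth(0, 0, NucleusClass.TUMOR_IC, False)] * 20)
        wsi = PseudoWSI(image=np.zeros((8, 8, 3), np.uint8),
                        mask=np.zeros((8, 8), np.uint8), nuclei=nuclei)
        assert wsi.true_index_ic == 80.0

    def test_seeded_determinism_and_partition(self):
        spec = WsiSpec(seed=5, width=768, height=768, context_side=256)
        a, b = generate_pseudo_wsi(spec), generate_pseudo_wsi(spec)
        np.testing.assert_array_equal(a.image, b.image)
        assert [(n.x, n.y, n.nucleus_class, n.marker_positive) for n in a.nuclei] \
            == [(n.x, n.y, n.nucleus_class, n.marker_positive) for n in b.nuclei]
        assert sum(a.class_counts().values()) == len(a.nuclei)

    def test_nuclei_inside_image_and_lymphocytes_negative(self):
        wsi = generate_pseudo_wsi(WsiSpec(seed=2, width=768, height=1024,
                                          context_side=256))
        for n in wsi.nuclei:
            assert 0 <= n.x < 768 and 0 <= n.y < 1024
            if n.nucleus_class is NucleusClass.LYMPHOCYTE:
                assert not n.marker_positive


class TestIO:
    def test_tile_roundtrip(self, tmp_path):
        tile = generate_tile(TileSpec(scenario="mixed", seed=9))
        img_path, _ = write_tile(tile, str(tmp_path), "t0")
        image, mask = read_tile_pair(img_path)
        np.testing.assert_array_equal(image, tile.image)
        np.testing.assert_array_equal(mask, tile.mask)

    def test_ledger_roundtrip(self, tmp_path):
        wsi = generate_pseudo_wsi(WsiSpec(seed=1, width=768, height=768,
                                          context_side=256))
        path = tmp_path / "ledger.csv"
        write_ledger(wsi.nuclei, str(path))
        back = read_ledger(str(path))
        assert len(back) == len(wsi.nuclei)
        assert back[0].nucleus_class == wsi.nuclei[0].nucleus_class

    def test_pseudo_wsi_roundtrip(self, tmp_path):
        wsi = generate_pseudo_wsi(WsiSpec(seed=1, width=768, height=768,
                                          context_side=256))
        write_pseudo_wsi(wsi, str(tmp_path), "w0")
        back = read_pseudo_wsi(str(tmp_path), "w0")
        np.testing.assert_array_equal(back.image, wsi.image)
        np.testing.assert_array_equal(back.mask, wsi.mask)
        assert abs(back.true_index_ic - wsi.true_index_ic) < 1e-9
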