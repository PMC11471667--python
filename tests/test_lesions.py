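"""Lesion pipeline: components, filters, paired stats, agreement."""

from collections import deque
from itertools import product

import numpy as np
import pytest

from petbench.lesions import (MaskProvider, agreement, connected_components,
                              evaluate_lesions, filter_lesions,
                              paired_roi_stats)
from petbench.suv import SUVVolume, to_suv
from petbench.types import DEFAULT_SPACING, PETVolume


def flood_fill_components(mask, connectivity=26):
    """Independent BFS labeling oracle (raster order of first voxels)."""
    mask = np.asarray(mask, bool)
    if connectivity == 26:
        neigh = [d for d in product((-1, 0, 1), repeat=3) if any(d)]
    else:
        neigh = [d for d in product((-1, 0, 1), repeat=3)
                 if sum(map(abs, d)) == 1]
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        if labels[idx]:
            continue
        nxt += 1
        q = deque([idx])
        labels[idx] = nxt
        while q:
            cur = q.popleft()
            for d in neigh:
                nb = tuple(np.add(cur, d))
                if all(0 <= n < s for n, s in zip(nb, mask.shape)) \
                        and mask[nb] and not labels[nb]:
                    labels[nb] = nxt
                    q.append(nb)
    return labels, nxt


def make_lesion_suv(lesion_values, meta, shape=(24, 32, 32)):
    """SUV volume + labels with spheres of given (center, diam_mm, suv)."""
    zz, yy, xx = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, DEFAULT_SPACING)),
        indexing="ij", sparse=True)
    values = np.full(shape, 0.2)
    labels = np.zeros(shape, dtype=np.int32)
    for i, (center, diam, suv) in enumerate(lesion_values, start=1):
        inside = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 \
            + (xx - center[2]) ** 2 <= (diam / 2) ** 2
        values[inside] = suv
        labels[inside] = i
    return SUVVolume(values, DEFAULT_SPACING, meta), labels


class TestConnectedComponents:
    def test_empty_mask_has_zero_components(self):
        labels, n = connected_components(np.zeros((4, 4, 4), bool))
        assert n == 0 and not labels.any()

    def test_corner_touching_voxels_merge_only_under_26(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = mask[2, 2, 2] = True
        _, n26 = connected_components(mask, connectivity=26)
        _, n6 = connected_components(mask, connectivity=6)
        assert n26 == 1 and n6 == 2

    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_flood_fill_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        mask = rng.random((12, 14, 16)) < 0.2
        labels, n = connected_components(mask, connectivity=connectivity)
        ref_labels, ref_n = flood_fill_components(mask, connectivity)
        assert n == ref_n
        np.testing.assert_array_equal(labels, ref_labels)

    def test_component_sizes_partition_foreground(self):
        rng = np.random.default_rng(5)
        mask = rng.random((10, 10, 10)) < 0.3
        labels, n = connected_components(mask)
        assert sum((labels == i).sum() for i in range(1, n + 1)) == mask.sum()

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError):
            connected_components(np.arange(8).reshape(2, 2, 2))


class TestFilterLesions:
    @pytest.mark.parametrize("center,diam,suv,retained", [
        # 6.54 mm max extent (2 slices, sphere centered between them)
        ((37.6, 44.9, 44.9), 5.0, 3.0, False),
        ((39.0, 44.0, 44.0), 10.0, 0.4, False),  # faint: mean SUV below 0.5
        ((39.0, 44.0, 44.0), 10.0, 3.0, True),   # passes both filters
    ])
    def test_size_and_uptake_thresholds(self, meta, center, diam, suv,
                                        retained):
        vol, labels = make_lesion_suv([(center, diam, suv)], meta)
        kept = filter_lesions(labels, vol)
        assert (1 in kept) == retained

    def test_two_slice_lesion_is_excluded_by_axial_extent(self, meta):
        # 2 slices x 3.27 mm = 6.54 mm < 7 mm in every direction
        labels = np.zeros((24, 32, 32), dtype=np.int32)
        labels[10:12, 10:11, 10:12] = 1
        values = np.full(labels.shape, 0.2)
        values[labels == 1] = 3.0
        vol = SUVVolume(values, DEFAULT_SPACING, meta)
        assert filter_lesions(labels, vol) == []

    def test_borderline_equality_retains(self, meta):
        # extents: 3 slices x 3.27 = 9.81 >= 7; mean SUV exactly 0.5
        labels = np.zeros((24, 32, 32), dtype=np.int32)
        labels[8:11, 10:13, 10:13] = 1
        values = np.full(labels.shape, 0.1)
        values[labels == 1] = 0.5
        vol = SUVVolume(values, DEFAULT_SPACING, meta)
        assert filter_lesions(labels, vol) == [1]

    def test_filtering_monotone_in_size_and_uptake(self, meta):
        vol_small, lab_small = make_lesion_suv(
            [((39.0, 44.0, 44.0), 9.0, 1.0)], meta)
        assert filter_lesions(lab_small, vol_small) == [1]
        # enlarging and brightening never flips retained -> excluded
        vol_big, lab_big = make_lesion_suv(
            [((39.0, 44.0, 44.0), 18.0, 4.0)], meta)
        assert filter_lesions(lab_big, vol_big) == [1]


class TestPairedStats:
    def _pet(self, suv_volume, meta):
        c_per_suv = meta.total_dose * 1000.0 / (meta.weight * 1000.0)
        return PETVolume(suv_volume.values * c_per_suv, suv_volume.spacing,
                         meta)

    def test_identical_volumes_give_identical_stats(self, meta):
        vol, labels = make_lesion_suv([((39.0, 44.0, 44.0), 12.0, 5.0)],
                                      meta)
        ft = self._pet(vol, meta)
        table = paired_roi_stats(ft, ft, labels)
        (lid, st_ft, st_den), = table.rows
        assert lid == 1
        assert st_ft == st_den

    def test_halved_volume_halves_suvmax(self, meta):
        vol, labels = make_lesion_suv([((39.0, 44.0, 44.0), 12.0, 5.0)],
                                      meta)
        ft = self._pet(vol, meta)
        den = ft.like(0.5 * ft.values)
        table = paired_roi_stats(ft, den, labels)
        (_, st_ft, st_den), = table.rows
        assert st_den.suv_max == pytest.approx(0.5 * st_ft.suv_max)
        assert st_den.suv_peak == pytest.approx(0.5 * st_ft.suv_peak)

    def test_two_lesion_phantom_has_exactly_retained_ids(self, meta):
        vol, labels = make_lesion_suv(
            [((26.0, 25.0, 25.0), 12.0, 5.0),   # retained
             ((52.0, 60.0, 60.0), 5.0, 3.0)],   # too small: filtered
            meta)
        ft = self._pet(vol, meta)
        kept = filter_lesions(labels, vol)
        table = paired_roi_stats(ft, ft, labels, lesion_ids=kept)
        assert [row[0] for row in table.rows] == [1]


class TestAgreement:
    def _table(self, meta, shift=0.0):
        vol, labels = make_lesion_suv(
            [((20.0, 25.0, 25.0), 12.0, 5.0),
             ((55.0, 60.0, 60.0), 14.0, 8.0),
             ((40.0, 30.0, 60.0), 10.0, 3.0)], meta)
        c_per_suv = meta.total_dose * 1000.0 / (meta.weight * 1000.0)
        ft = PETVolume(vol.values * c_per_suv, vol.spacing, meta)
        den = ft.like(ft.values + shift * c_per_suv)
        return paired_roi_stats(ft, den, labels)

    def test_identity_denoiser_zero_bias_zero_iqr(self, meta):
        rep = agreement(self._table(meta), "suv_max")
        assert rep.median_bias == 0.0 and rep.iqr == 0.0
        assert rep.one_minus_r2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_suv_shift_appears_as_bias_only(self, meta):
        rep = agreement(self._table(meta, shift=0.2), "suv_max")
        assert rep.median_bias == pytest.approx(0.2)
        assert rep.iqr == pytest.approx(0.0, abs=1e-12)

    def test_random_perturbations_match_brute_force(self, meta):
        from petbench.metrics import bland_altman, one_minus_r2
        rng = np.random.default_rng(8)
        table = self._table(meta)
        # perturb the denoised column directly
        pairs = [(ft.suv_max, ft.suv_max + rng.normal(0, 0.3))
                 for _, ft, _ in table.rows]
        bias, iqr = bland_altman(pairs)
        d = np.sort([b - a for a, b in pairs])
        assert bias == pytest.approx(np.median(d))
        assert iqr == pytest.approx(
            np.percentile(d, 75) - np.percentile(d, 25))
        assert 0.0 <= one_minus_r2(pairs) <= 1.0

    def test_empty_table_rejected(self):
        from petbench.lesions import LesionTable
        with pytest.raises(ValueError, match="no evaluable"):
            agreement(LesionTable(), "suv_max")


class TestEndToEnd:
    def test_pipeline_recovers_constructed_lesion_count(self, small_study):
        # one >= 7 mm, SUV-4 lesion built into the phantom
        den = small_study[90]
        res = evaluate_lesions(small_study, den,
                               provider=MaskProvider("ground_truth"))
        assert res["n_lesions"] == 1

    def test_ft_vs_itself_yields_perfect_agreement(self, tiny_dataset):
        studies = [s for s in tiny_dataset["test"]]
        pairs_max, pairs_peak = [], []
        for s in studies:
            res = evaluate_lesions(s, s[90])
            if res["suv_max"] is not None:
                assert res["suv_max"].median_bias == 0.0
                assert res["suv_max"].iqr == 0.0
                assert res["suv_max"].one_minus_r2 == pytest.approx(
                    0.0, abs=1e-12)
                assert res["suv_peak"].median_bias == 0.0

    def test_suv_threshold_provider_finds_hot_lesion(self, small_study):
        res = evaluate_lesions(small_study, small_study[90],
                               provider=MaskProvider("suv_threshold",
                                                     threshold=2.5))
        assert res["n_lesions"] >= 1
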