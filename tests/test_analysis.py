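"""Atlas-space analytics: correspondence, cell assignment, occupancy, volumes."""

import numpy as np
import pandas as pd
import pytest

from atlasforge.analysis import (
    assign_cells,
    growth_stats,
    label_correspondence,
    occupancy,
    region_matrix,
    region_volumes,
)
from atlasforge.ontology import (
    AnnotationVolume,
    Ontology,
    RegionNode,
    make_synthetic_ontology,
)
from atlasforge.synthetic import make_cells
from atlasforge.volume import Volume3D, resample


def _annot(values, spacing=(10, 10, 10), n_regions=None):
    n = n_regions or int(values.max())
    return AnnotationVolume(Volume3D(values.astype(np.uint16), spacing),
                            make_synthetic_ontology(max(n, 1)))


class TestCorrespondence:
    def test_identical_annotations_are_diagonal(self, phantom32):
        _, annot, _ = phantom32
        av = AnnotationVolume(annot, make_synthetic_ontology(3))
        table = label_correspondence(av, av, min_voxels=1)
        assert (table["label_a"] == table["label_b"]).all()
        counts = {r.label_a: r.voxel_count for r in table.itertuples()}
        for label, count in counts.items():
            assert count == int((annot.values == label).sum())

    def test_half_and_half_split_counts(self):
        a = np.ones((10, 10, 10))
        b = np.full((10, 10, 10), 10)
        b[:, :, 5:] = 20
        table = label_correspondence(_annot(a, n_regions=1), _annot(b, n_regions=19),
                                     min_voxels=1)
        rows = {(r.label_a, r.label_b): r.voxel_count for r in table.itertuples()}
        assert rows == {(1, 10): 500, (1, 20): 500}

    def test_threshold_removes_exactly_small_rows(self):
        a = np.ones((10, 10, 10))
        b = np.full((10, 10, 10), 10)
        b[0, 0, :3] = 20  # a 3-voxel sliver
        full = label_correspondence(_annot(a, n_regions=1), _annot(b, n_regions=19),
                                    min_voxels=1)
        cut = label_correspondence(_annot(a, n_regions=1), _annot(b, n_regions=19),
                                   min_voxels=250)
        assert len(full) == 2 and len(cut) == 1
        assert cut.iloc[0]["voxel_count"] >= 250

    def test_unthresholded_total_is_doubly_labeled_count(self, phantom32):
        _, annot, _ = phantom32
        av = AnnotationVolume(annot, make_synthetic_ontology(3))
        shifted = annot.like(np.roll(annot.values, 2, axis=1))
        bv = AnnotationVolume(shifted, make_synthetic_ontology(3))
        table = label_correspondence(av, bv, min_voxels=1)
        both = (annot.values > 0) & (shifted.values > 0)
        assert table["voxel_count"].sum() == both.sum()
        assert table.attrs["total_doubly_labeled"] == both.sum()

    def test_grid_mismatch_rejected(self, phantom32):
        _, annot, _ = phantom32
        av = AnnotationVolume(annot, make_synthetic_ontology(3))
        other = AnnotationVolume(
            Volume3D(annot.values[:16].copy(), annot.spacing),
            make_synthetic_ontology(3))
        with pytest.raises(ValueError, match="grid"):
            label_correspondence(av, other)


class TestAssignCells:
    def test_cell_at_voxel_center(self):
        vals = np.zeros((8, 8, 8), dtype=np.uint16)
        vals[4, 4, 4] = 2
        av = _annot(vals, spacing=(10, 10, 10), n_regions=2)
        cells = pd.DataFrame({"z_um": [40.0], "y_um": [40.0], "x_um": [40.0],
                              "subclass": ["s"], "cell_class": ["s"]})
        out = assign_cells(cells, av)
        assert out["region_id"].tolist() == [2]

    def test_synthetic_cells_fully_recover_labels(self, phantom48):
        _, annot, _ = phantom48
        av = AnnotationVolume(annot, make_synthetic_ontology(4))
        cells = make_cells(annot, {1: 30000, 2: 30000, 4: 30000}, {}, seed=6)
        out = assign_cells(cells, av)
        assert (out["region_id"] == out["true_label"]).mean() == 1.0
        assert out.attrs["n_out_of_bounds"] == 0

    def test_out_of_bounds_cell_reported_as_background(self, phantom32):
        _, annot, _ = phantom32
        av = AnnotationVolume(annot, make_synthetic_ontology(3))
        cells = pd.DataFrame({"z_um": [-500.0], "y_um": [0.0], "x_um": [0.0],
                              "subclass": ["s"], "cell_class": ["s"]})
        out = assign_cells(cells, av)
        assert out["region_id"].tolist() == [0]
        assert out.attrs["n_out_of_bounds"] == 1


class TestRegionMatrix:
    def test_rows_sum_to_one(self, phantom48):
        _, annot, _ = phantom48
        av = AnnotationVolume(annot, make_synthetic_ontology(4))
        cells = make_cells(annot, {1: 40000, 2: 40000},
                           {1: {"GABA/Sst": 0.6, "GABA/Pvalb": 0.4},
                            2: {"Glut/L5": 1.0}}, seed=2)
        mat = region_matrix(assign_cells(cells, av))
        np.testing.assert_allclose(mat.sum(axis=1).to_numpy(), 1.0, atol=1e-9)

    def test_single_region_subclass_is_indicator_row(self, phantom32):
        _, annot, _ = phantom32
        av = AnnotationVolume(annot, make_synthetic_ontology(3))
        cells = make_cells(annot, {2: 60000}, {2: {"GABA/Sst": 1.0}}, seed=3)
        mat = region_matrix(assign_cells(cells, av))
        row = mat.loc["GABA/Sst"]
        assert row[2] == 1.0 and row.sum() == 1.0

    def test_uniform_cells_split_by_volume_within_binomial_noise(self):
        vals = np.ones((20, 20, 20), dtype=np.uint16)
        vals[:, :, 10:] = 2  # two equal-volume regions
        av = _annot(vals, spacing=(20, 20, 20), n_regions=2)
        rate = 30000.0
        cells = make_cells(av.labels, {1: rate, 2: rate},
                           {1: {"s": 1.0}, 2: {"s": 1.0}}, seed=5)
        mat = region_matrix(assign_cells(cells, av))
        n = len(cells)
        sigma = np.sqrt(0.25 / n)
        assert abs(mat.loc["s", 1] - 0.5) < 3 * sigma


class TestOccupancy:
    def _setup(self, seed=0, p=0.3):
        rng = np.random.default_rng(seed)
        hi = Volume3D((rng.random((32, 32, 32)) < p).astype(np.int64), (5, 5, 5))
        pooled = resample(hi, (20, 20, 20), "sum")  # factor 4 per axis -> 64
        vals = np.ones(pooled.shape, dtype=np.uint16)
        vals[:, :, 4:] = 2
        return hi, pooled, _annot(vals, spacing=(20, 20, 20), n_regions=2)

    def test_zero_counts_zero_ratios(self):
        _, pooled, annot = self._setup()
        table = occupancy(pooled.like(np.zeros_like(pooled.values)), annot, 64)
        assert (table["ratio"] == 0).all()

    def test_saturated_region_fraction_is_one(self):
        _, pooled, annot = self._setup()
        full = pooled.like(np.full_like(pooled.values, 64))
        table = occupancy(full, annot, 64)
        np.testing.assert_allclose(table["normalized_fraction"], 1.0)

    def test_positive_totals_conserved(self):
        hi, pooled, annot = self._setup(seed=3)
        table = occupancy(pooled, annot, 64)
        assert table["positive_voxels"].sum() == hi.values.sum()

    def test_count_exceeding_factor_rejected(self):
        _, pooled, annot = self._setup()
        with pytest.raises(ValueError, match="aggregation_factor"):
            occupancy(pooled, annot, 2)


class TestVolumes:
    def test_voxel_count_to_mm3(self):
        vals = np.zeros((10, 10, 10), dtype=np.uint16)
        vals[0, 0, :10] = 1
        av = _annot(vals, spacing=(20, 20, 20), n_regions=1)
        table = region_volumes(av)
        np.testing.assert_allclose(table.loc[0, "volume_mm3"], 10 * 0.02 ** 3)

    def test_children_sum_to_parent_volume(self, phantom48):
        _, annot, _ = phantom48
        av = AnnotationVolume(annot, make_synthetic_ontology(4))
        leaves = region_volumes(av)
        rolled = region_volumes(av, level=0)
        np.testing.assert_allclose(rolled["volume_mm3"].sum(),
                                   leaves["volume_mm3"].sum(), rtol=1e-12)

    def test_growth_z_zero_at_mean(self):
        stats = growth_stats([4.0, 6.0], 5.0)
        assert stats["mean"] == 5.0
        assert stats["sd"] == pytest.approx(np.sqrt(2))
        assert stats["z"] == 0.0

    def test_growth_z_in_sd_units(self):
        stats = growth_stats([400.0, 420.0, 440.0], 460.0)
        assert stats["z"] == pytest.approx((460 - 420) / 20)
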