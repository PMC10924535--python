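import numpy as np
import pandas as pd
import pytest

from vlsm.errors import GridMismatchError, ValidationError
from vlsm.parcellation import (
    ParcelAtlas,
    coverage,
    heatmap_matrix,
    load_atlas,
    save_atlas,
    top_parcels,
)
from vlsm.simulate import SimulationConfig, make_atlas, make_template


def toy_atlas():
    """3 parcels of known sizes on a 4x4x4 grid: 100% labelled."""
    labels = np.zeros((4, 4, 4), dtype=np.int32)
    labels[:2] = 1  # 32 voxels
    labels[2] = 2  # 16 voxels
    labels[3] = 3  # 16 voxels
    table = pd.DataFrame(
        {
            "label": [1, 2, 3],
            "name": ["front", "mid", "back"],
            "hemisphere": ["L", "R", "R"],
            "parcel_class": ["cortical", "cortical", "subcortical"],
        }
    )
    return ParcelAtlas(labels=labels, parcel_table=table)


def test_coverage_definition_and_zero_retention():
    atlas = toy_atlas()
    sig = np.zeros((4, 4, 4), bool)
    sig[0] = True  # 16 of parcel 1's 32 voxels
    table = coverage(sig, atlas, "memory", 0.05)
    by_label = table.set_index("label")
    assert by_label.loc[1, "coverage_percent"] == 50.0
    assert by_label.loc[2, "coverage_percent"] == 0.0  # zero-coverage parcel kept
    assert by_label.loc[3, "significant_voxels"] == 0
    empty = coverage(np.zeros((4, 4, 4), bool), atlas, "memory", 0.05)
    assert (empty[empty["label"] > 0]["coverage_percent"] == 0).all()
    full = coverage(np.ones((4, 4, 4), bool), atlas, "memory", 0.05)
    assert (full[full["label"] > 0]["coverage_percent"] == 100.0).all()


def test_coverage_conserves_significant_voxels():
    rng = np.random.default_rng(0)
    config = SimulationConfig(grid_shape=(16, 16, 16), n_parcels=5, seed=0)
    space = make_template(config)
    atlas = make_atlas(space, 5, seed=2)
    for trial in range(5):
        sig = rng.random((16, 16, 16)) < 0.3
        table = coverage(sig, atlas, "d", 0.2)
        labelled = sig & (atlas.labels > 0)
        assert table[table["label"] > 0]["significant_voxels"].sum() == labelled.sum()
        # residual row picks up everything outside the parcels, exactly
        assert table["significant_voxels"].sum() == sig.sum()


def test_coverage_grid_mismatch():
    with pytest.raises(GridMismatchError):
        coverage(np.zeros((3, 3, 3), bool), toy_atlas(), "d", 0.05)


def test_top_parcels_ordering_and_tie_breaks():
    atlas = toy_atlas()
    sig = np.zeros((4, 4, 4), bool)
    sig[2] = True  # parcel 2 at 100%
    sig[0, :2] = True  # parcel 1 (32 vox) at 25%
    sig[3, :1] = True  # parcel 3 (16 vox) at 25%
    table = coverage(sig, atlas, "d", 0.2)
    ranked = top_parcels(table, 15)
    assert ranked["label"].tolist() == [2, 1, 3]  # tie at 25% -> larger parcel first
    assert (ranked["coverage_percent"].diff().dropna() <= 0).all()
    assert len(top_parcels(table, 2)) == 2
    assert len(top_parcels(table, 50)) == 3  # n beyond parcel count -> all
    with pytest.raises(ValidationError):
        top_parcels(table, 0)


def test_heatmap_matrix_union_and_ordering():
    atlas = toy_atlas()
    sig_a = np.zeros((4, 4, 4), bool)
    sig_a[0] = True  # parcel 1 at 50%
    sig_b = np.zeros((4, 4, 4), bool)
    sig_b[3] = True  # parcel 3 at 100%
    tables = {
        "memory": coverage(sig_a, atlas, "memory", 0.2),
        "language": coverage(sig_b, atlas, "language", 0.2),
    }
    matrix = heatmap_matrix(tables, top_n=1)
    assert set(matrix.columns) == {"memory", "language"}
    assert matrix.shape[0] == 2  # union of disjoint per-domain top-1 sets
    assert matrix.index[0] == "back"  # ordered by max coverage across domains
    assert matrix.loc["back", "language"] == 100.0
    assert matrix.loc["back", "memory"] == 0.0  # absent domain filled with 0
    single = heatmap_matrix({"memory": tables["memory"]}, top_n=None)
    assert single["memory"].tolist() == sorted(
        single["memory"].tolist(), reverse=True
    )
    # empty-significance domain keeps an all-zero column
    empty = coverage(np.zeros((4, 4, 4), bool), atlas, "visuospatial", 0.2)
    matrix = heatmap_matrix({**tables, "visuospatial": empty}, top_n=None)
    assert (matrix["visuospatial"] == 0).all()


def test_heatmap_matrix_class_filter_and_atlas_consistency():
    atlas = toy_atlas()
    sig = np.ones((4, 4, 4), bool)
    table = coverage(sig, atlas, "memory", 0.2)
    cortical = heatmap_matrix({"memory": table}, parcel_class="cortical", atlas=atlas, top_n=None)
    assert set(cortical.index) == {"front", "mid"}
    other = table.copy()
    other = other[other["label"] != 2]
    with pytest.raises(ValidationError):
        heatmap_matrix({"a": table, "b": other}, top_n=None)


def test_coverage_monotone_in_alpha():
    """Looser alpha -> superset of significant voxels -> coverage can only grow."""
    from vlsm.inference import PValueMap, threshold_map

    rng = np.random.default_rng(3)
    atlas = toy_atlas()
    values = rng.random((4, 4, 4))
    pmap = PValueMap(values=values, valid=np.ones((4, 4, 4), bool), method="x")
    loose = coverage(threshold_map(pmap, 0.2), atlas, "d", 0.2)
    strict = coverage(threshold_map(pmap, 0.05), atlas, "d", 0.05)
    assert (
        loose["coverage_percent"].to_numpy() >= strict["coverage_percent"].to_numpy()
    ).all()


def test_atlas_io_round_trip(tmp_path):
    config = SimulationConfig(grid_shape=(16, 16, 16), n_parcels=4, seed=1)
    space = make_template(config)
    atlas = make_atlas(space, 4, seed=5)
    save_atlas(atlas, space, tmp_path / "labels.nii.gz", tmp_path / "parcels.csv")
    loaded = load_atlas(tmp_path / "labels.nii.gz", tmp_path / "parcels.csv")
    np.testing.assert_array_equal(loaded.labels, atlas.labels)
    pd.testing.assert_frame_equal(loaded.parcel_table, atlas.parcel_table)


def test_atlas_table_must_cover_labels():
    labels = np.ones((2, 2, 2), dtype=np.int32)
    labels[0, 0, 0] = 5
    table = pd.DataFrame(
        {"label": [1], "name": ["a"], "hemisphere": ["L"], "parcel_class": ["cortical"]}
    )
    with pytest.raises(ValidationError, match="missing"):
        ParcelAtlas(labels=labels, parcel_table=table)
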