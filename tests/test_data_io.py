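import numpy as np
import pytest

from localbalance.data_io import (
    GROUP_HI,
    GROUP_LOW,
    ConfigError,
    DataError,
    PreprocessSpec,
    apply_preprocess,
    binarize_by_target,
    drop_zero_features,
    map_labels,
    normalize_total,
    read_arff,
    read_delimited,
    scale_columns,
    write_delimited,
)

from conftest import make_ds


# ---------------------------------------------------------------------------
# delimited loading
# ---------------------------------------------------------------------------

def test_read_delimited_small_csv(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("f1,f2,grp\n1,2,A\n3,4,B\n5,6,A\n")
    ds = read_delimited(p, label_column="grp")
    assert ds.n_samples == 3
    assert ds.matrix.n_features == 2
    # lexicographically smaller raw label -> Low
    assert list(ds.labels) == [GROUP_LOW, GROUP_HI, GROUP_LOW]
    assert list(ds.raw_labels) == ["A", "B", "A"]
    assert ds.sample_ids == ["s0001", "s0002", "s0003"]


def test_read_delimited_leading_id_column(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("id,f1,grp\nx1,1,A\nx2,2,B\n")
    ds = read_delimited(p, label_column="grp")
    assert ds.sample_ids == ["x1", "x2"]
    assert ds.feature_ids == ["f1"]


def test_read_delimited_non_numeric_cell_is_an_error(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("f1,f2,grp\n1,2,A\n3,oops,B\n")
    with pytest.raises(DataError, match="oops"):
        read_delimited(p, label_column="grp")


def test_read_delimited_missing_label_column(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("f1,f2\n1,2\n")
    with pytest.raises(ConfigError, match="label column"):
        read_delimited(p, label_column="grp")


def test_read_delimited_rejects_missing_values(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("f1,f2,grp\n1,,A\n3,4,B\n")
    with pytest.raises(DataError, match="missing value"):
        read_delimited(p, label_column="grp")


def test_roundtrip_preserves_everything(tmp_path):
    rng = np.random.default_rng(0)
    ds = make_ds(rng.normal(size=(5, 4)), ["Low", "Hi", "Low", "Hi", "Hi"])
    p = tmp_path / "rt.csv"
    write_delimited(ds, p)
    back = read_delimited(p, label_column="class", label_map={"Low": "Low", "Hi": "Hi"})
    assert back.sample_ids == ds.sample_ids
    assert back.feature_ids == ds.feature_ids
    assert list(back.labels) == list(ds.labels)
    np.testing.assert_array_equal(back.X, ds.X)


# ---------------------------------------------------------------------------
# ARFF loading
# ---------------------------------------------------------------------------

ARFF_MINI = """@relation mini
@attribute f1 numeric
@attribute f2 numeric
@attribute cls {a,b}
@data
1.0,2.0,a
3.0,4.0,b
"""


def test_read_arff_minimal(tmp_path):
    p = tmp_path / "m.arff"
    p.write_text(ARFF_MINI)
    ds = read_arff(p, label_attribute="cls")
    assert ds.n_samples == 2
    assert list(ds.labels) == [GROUP_LOW, GROUP_HI]
    np.testing.assert_array_equal(ds.X, [[1.0, 2.0], [3.0, 4.0]])


def test_read_arff_missing_label_attribute(tmp_path):
    p = tmp_path / "m.arff"
    p.write_text(ARFF_MINI)
    with pytest.raises(ConfigError, match="label attribute"):
        read_arff(p, label_attribute="nope")


# ---------------------------------------------------------------------------
# label mapping / binarization
# ---------------------------------------------------------------------------

def test_binarize_by_target():
    ds = make_ds(np.zeros((5, 2)), ["1", "2", "4", "4", "7"])
    out = binarize_by_target(ds, "4")
    assert list(out.labels) == [GROUP_HI, GROUP_HI, GROUP_LOW, GROUP_LOW, GROUP_HI]
    assert list(out.raw_labels) == ["1", "2", "4", "4", "7"]


def test_binarize_absent_target_errors():
    ds = make_ds(np.zeros((2, 2)), ["1", "2"])
    with pytest.raises(ConfigError, match="absent"):
        binarize_by_target(ds, "9")


def test_map_labels_explicit_mapping():
    ds = make_ds(np.zeros((3, 1)), ["pos", "neg", "pos"])
    out = map_labels(ds, {"pos": "Hi", "neg": "Low"})
    assert list(out.labels) == [GROUP_HI, GROUP_LOW, GROUP_HI]


def test_map_labels_auto_requires_two_classes():
    ds = make_ds(np.zeros((3, 1)), ["a", "b", "c"])
    with pytest.raises(ConfigError, match="exactly 2"):
        map_labels(ds)


# ---------------------------------------------------------------------------
# normalization / scaling / zero-feature removal
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "mode,expected",
    [("percent100", [20.0, 30.0, 50.0]), ("unit1", [0.2, 0.3, 0.5])],
)
def test_normalize_total_closed_form(mode, expected):
    ds = make_ds([[2.0, 3.0, 5.0]] * 2, ["Low", "Hi"])
    out = normalize_total(ds, mode)
    np.testing.assert_allclose(out.X[0], expected)


def test_normalize_total_row_sum_identity():
    rng = np.random.default_rng(1)
    ds = make_ds(rng.uniform(0.1, 5.0, (7, 6)), ["Low", "Hi"] * 3 + ["Low"])
    np.testing.assert_allclose(normalize_total(ds, "percent100").X.sum(axis=1), 100.0)
    np.testing.assert_allclose(normalize_total(ds, "unit1").X.sum(axis=1), 1.0)


def test_normalize_total_zero_row_names_the_sample():
    ds = make_ds([[1.0, 2.0], [0.0, 0.0]], ["Low", "Hi"])
    with pytest.raises(DataError, match="s1"):
        normalize_total(ds, "unit1")


def test_scale_columns_closed_form():
    ds = make_ds([[1.0], [2.0], [3.0]], ["Low", "Hi", "Low"])
    np.testing.assert_allclose(scale_columns(ds).X[:, 0], [-1.0, 0.0, 1.0])


def test_scale_columns_definition_and_idempotence():
    rng = np.random.default_rng(2)
    ds = make_ds(rng.normal(2.0, 3.0, (20, 5)), ["Low", "Hi"] * 10)
    out = scale_columns(ds)
    assert np.all(np.abs(out.X.mean(axis=0)) < 1e-10)
    assert np.all(np.abs(out.X.std(axis=0, ddof=1) - 1) < 1e-10)
    again = scale_columns(out)
    np.testing.assert_allclose(again.X, out.X, atol=1e-10)


def test_scale_columns_drops_constant_columns_with_warning():
    ds = make_ds([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0]], ["Low", "Hi", "Low"])
    with pytest.warns(UserWarning, match="constant"):
        out = scale_columns(ds)
    assert out.feature_ids == ["f0"]


def test_drop_zero_features():
    ds = make_ds([[1.0, 0.0, 2.0], [3.0, 0.0, 0.0]], ["Low", "Hi"])
    out = drop_zero_features(ds)
    assert out.feature_ids == ["f0", "f2"]
    # idempotent, and identity when nothing is all-zero
    assert drop_zero_features(out) is out


def test_apply_preprocess_order():
    # normalize then scale: rows of the normalized matrix sum to 100 before scaling
    rng = np.random.default_rng(3)
    ds = make_ds(rng.uniform(0.5, 2.0, (10, 4)), ["Low", "Hi"] * 5)
    spec = PreprocessSpec(scale=True, normalize_total="percent100")
    out = apply_preprocess(ds, spec)
    ref = scale_columns(normalize_total(ds, "percent100"))
    np.testing.assert_allclose(out.X, ref.X)
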