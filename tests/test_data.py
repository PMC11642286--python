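"""Response-table loading, validation, standardization and moments."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bcfa
from bcfa.exceptions import (
    DegenerateVarianceError,
    InsufficientDataError,
    ValidationError,
)


def _write_csv(path, values):
    pd.DataFrame(values, columns=list(bcfa.data.DEFAULT_ITEM_LABELS)).to_csv(
        path, index=False
    )


class TestLoadResponses:
    def test_well_formed_csv(self, tmp_path):
        rng = np.random.default_rng(0)
        values = rng.integers(1, 9, size=(3, 12))
        path = tmp_path / "resp.csv"
        _write_csv(path, values)
        rm = bcfa.load_responses(path)
        assert rm.values.shape == (3, 12)
        np.testing.assert_array_equal(rm.values, values)

    def test_out_of_range_entry_named(self, tmp_path):
        values = np.ones((3, 12), dtype=int)
        values[1, 4] = 9
        path = tmp_path / "resp.csv"
        _write_csv(path, values)
        with pytest.raises(ValidationError, match="item5"):
            bcfa.load_responses(path)

    def test_listwise_deletion_logged(self, tmp_path, caplog):
        values = np.full((5, 12), 4.0)
        values[2, 7] = np.nan
        path = tmp_path / "resp.csv"
        _write_csv(path, values)
        with caplog.at_level(logging.INFO, logger="bcfa.data"):
            rm = bcfa.load_responses(path)
        assert rm.values.shape == (4, 12)
        assert any("dropped 1" in rec.message for rec in caplog.records)

    def test_non_numeric_entry_rejected(self, tmp_path):
        path = tmp_path / "resp.csv"
        path.write_text(
            ",".join(bcfa.data.DEFAULT_ITEM_LABELS)
            + "\n"
            + ",".join(["3"] * 11 + ["oops"])
            + "\n"
        )
        with pytest.raises(ValidationError, match="item12"):
            bcfa.load_responses(path)

    def test_csv_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(1)
        rm = bcfa.ResponseMatrix(values=rng.integers(1, 9, size=(7, 12)))
        path = tmp_path / "out.csv"
        rm.to_csv(path)
        back = bcfa.load_responses(path)
        np.testing.assert_array_equal(back.values, rm.values)


class TestResponseMatrixInvariants:
    def test_range_check_on_construction(self):
        bad = np.full((2, 12), 3.0)
        bad[0, 0] = 0.0
        with pytest.raises(ValidationError):
            bcfa.ResponseMatrix(values=bad)

    def test_subscale_map_must_cover_items(self):
        with pytest.raises(ValidationError, match="subscale_map"):
            bcfa.ResponseMatrix(
                values=np.full((2, 3), 2.0),
                item_labels=("a", "b", "c"),
                subscale_map={"a": "Knowledge", "b": "Coping"},
            )

    def test_minimum_shape(self):
        with pytest.raises(ValidationError):
            bcfa.ResponseMatrix(values=np.full((2, 1), 2.0), item_labels=("a",),
                                subscale_map={"a": "Knowledge"})


class TestStandardize:
    def test_definition_small_column(self):
        rm = bcfa.ResponseMatrix(
            values=np.array([[2.0, 1], [4, 2], [6, 3]]),
            item_labels=("a", "b"),
            subscale_map={"a": "Knowledge", "b": "Knowledge"},
        )
        std = bcfa.standardize(rm)
        np.testing.assert_allclose(std.values[:, 0], [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(std.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(std.values.std(axis=0, ddof=1), 1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        rm = bcfa.ResponseMatrix(values=rng.integers(1, 9, size=(30, 12)).astype(float))
        once = bcfa.standardize(rm)
        again = bcfa.standardize(
            bcfa.ResponseMatrix(values=once.values, likert=False)
        )
        np.testing.assert_allclose(again.values, once.values, atol=1e-12)

    def test_constant_column_rejected(self):
        rm = bcfa.ResponseMatrix(
            values=np.column_stack([np.full(3, 5.0), [1.0, 2, 3]]),
            item_labels=("a", "b"),
            subscale_map={"a": "Knowledge", "b": "Knowledge"},
        )
        with pytest.raises(DegenerateVarianceError, match="a"):
            bcfa.standardize(rm)

    @given(
        a=st.floats(min_value=0.1, max_value=50),
        b=st.floats(min_value=-20, max_value=20),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(20, 2))
        rm1 = bcfa.ResponseMatrix(values=base, likert=False,
                                  item_labels=("a", "b"),
                                  subscale_map={"a": "Knowledge", "b": "Knowledge"})
        scaled = base.copy()
        scaled[:, 0] = a * base[:, 0] + b
        rm2 = bcfa.ResponseMatrix(values=scaled, likert=False,
                                  item_labels=("a", "b"),
                                  subscale_map={"a": "Knowledge", "b": "Knowledge"})
        np.testing.assert_allclose(
            bcfa.standardize(rm1).values[:, 0],
            bcfa.standardize(rm2).values[:, 0],
            atol=1e-8,
        )


class TestSampleCovariance:
    def _std(self, values):
        rm = bcfa.ResponseMatrix(
            values=values, likert=False,
            item_labels=tuple(f"c{i}" for i in range(values.shape[1])),
            subscale_map={f"c{i}": "Knowledge" for i in range(values.shape[1])},
        )
        return bcfa.standardize(rm)

    def test_hand_computation_3x2(self):
        y = np.array([[1.0, 2.0], [2.0, 1.0], [6.0, 3.0]])
        std = self._std(y)
        got = bcfa.sample_covariance(std)
        z = std.values - std.values.mean(axis=0)
        expected = np.array(
            [
                [np.dot(z[:, 0], z[:, 0]), np.dot(z[:, 0], z[:, 1])],
                [np.dot(z[:, 1], z[:, 0]), np.dot(z[:, 1], z[:, 1])],
            ]
        ) / 3.0
        np.testing.assert_allclose(got, expected, atol=1e-12)
        # ML divisor: standardized columns have variance (n-1)/n
        np.testing.assert_allclose(np.diag(got), 2.0 / 3.0)

    def test_perfectly_correlated_columns(self):
        base = np.array([1.0, 2.0, 4.0])
        std = self._std(np.column_stack([base, base]))
        cov = bcfa.sample_covariance(std)
        assert cov[0, 1] == pytest.approx(cov[0, 0])

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        std = self._std(rng.normal(size=(15, 4)))
        cov = bcfa.sample_covariance(std)
        np.testing.assert_array_equal(cov, cov.T)

    def test_single_row_rejected(self):
        with pytest.raises(InsufficientDataError):
            bcfa.sample_covariance(np.array([[1.0, 2.0]]))
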