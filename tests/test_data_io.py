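"""Reading, validating and summarizing survival tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survcontour.data import (
    ColumnRoles,
    SurvivalDataset,
    read_dataset,
    summarize_covariate,
    validate_dataset,
    write_dataset,
)
from survcontour.errors import EmptyDataError, ParseError, RoleError


def _write(tmp_path, text, name="d.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestColumnRoles:
    def test_right_mode(self):
        r = ColumnRoles(time="t", event="e", predictor="x")
        assert not r.interval_mode

    def test_exactly_one_mode_enforced(self):
        with pytest.raises(RoleError):
            ColumnRoles(time="t", interval_left="l", interval_right="r",
                        event="e", predictor="x")
        with pytest.raises(RoleError):
            ColumnRoles(event="e", predictor="x")
        with pytest.raises(RoleError):
            ColumnRoles(interval_left="l", event="e", predictor="x")

    def test_predictor_cannot_be_adjuster(self):
        with pytest.raises(RoleError):
            ColumnRoles(time="t", event="e", predictor="x", adjusters=("x",))


class TestReadDataset:
    ROLES = ColumnRoles(time="t", event="e", predictor="x")

    def test_three_row_parse(self, tmp_path):
        p = _write(tmp_path, "t,e,x\n1,1,0.5\n2,0,1.5\n3,1,2.5\n")
        ds = read_dataset(p, self.ROLES)
        assert ds.n == 3
        assert np.array_equal(ds.times, [1, 2, 3])
        assert np.array_equal(ds.events, [1, 0, 1])

    def test_missing_role_column_named_in_error(self, tmp_path):
        p = _write(tmp_path, "t,e,x\n1,1,0.5\n")
        with pytest.raises(RoleError, match="foo"):
            read_dataset(p, ColumnRoles(time="t", event="e", predictor="foo"))

    def test_missing_value_row_dropped_and_counted(self, tmp_path):
        p = _write(tmp_path, "t,e,x\n1,1,0.5\n2,0,\n3,1,2.5\n")
        ds = read_dataset(p, self.ROLES)
        assert ds.n == 2
        assert ds.n_dropped == 1

    def test_non_numeric_time_is_parse_error_with_row(self, tmp_path):
        p = _write(tmp_path, "t,e,x\n1,1,0.5\noops,0,1.0\n")
        with pytest.raises(ParseError, match="row 1"):
            read_dataset(p, self.ROLES)

    def test_zero_usable_rows(self, tmp_path):
        p = _write(tmp_path, "t,e,x\n,1,0.5\n")
        with pytest.raises(EmptyDataError):
            read_dataset(p, self.ROLES)

    def test_interval_sentinel_inf(self, tmp_path):
        p = _write(tmp_path, "l,r,e,x\n1,2,1,0.1\n3,Inf,0,0.2\n4,,0,0.3\n")
        roles = ColumnRoles(interval_left="l", interval_right="r", event="e", predictor="x")
        ds = read_dataset(p, roles)
        assert ds.n == 3
        assert np.isinf(ds.interval_right[1]) and np.isinf(ds.interval_right[2])

    def test_tsv_delimiter_from_extension(self, tmp_path):
        p = _write(tmp_path, "t\te\tx\n1\t1\t0.5\n", name="d.tsv")
        assert read_dataset(p, self.ROLES).n == 1

    def test_categorical_autodetect_and_override(self, tmp_path):
        body = "\n".join(f"{i},1,{i * 0.1},{i % 3},{'a' if i % 2 else 'b'}" for i in range(1, 31))
        p = _write(tmp_path, "t,e,x,score,grp\n" + body)
        roles = ColumnRoles(time="t", event="e", predictor="x", adjusters=("score", "grp"))
        ds = read_dataset(p, roles)
        # 3 distinct small integers -> categorical; strings -> categorical
        assert ds.adjusters["score"].kind == "categorical"
        assert ds.adjusters["grp"].kind == "categorical"
        ds2 = read_dataset(p, roles, categorical_overrides={"score": "continuous"})
        assert ds2.adjusters["score"].kind == "continuous"

    def test_roundtrip(self, tmp_path, ph_dataset):
        roles = ph_dataset.default_roles()
        p = tmp_path / "rt.csv"
        write_dataset(ph_dataset, p, roles)
        back = read_dataset(p, roles)
        assert np.allclose(back.times, ph_dataset.times)
        assert np.array_equal(back.events, ph_dataset.events)
        assert np.allclose(back.predictor, ph_dataset.predictor)


class TestValidateDataset:
    def test_negative_time_cites_row(self):
        ds = SurvivalDataset.from_arrays(
            times=[1, 2, 3, 4, 5, -1], events=[1] * 6, predictor=np.arange(6.0)
        )
        report = validate_dataset(ds)
        codes = {v.code: v for v in report.violations}
        assert not report.ok
        assert codes["negative_time"].rows == (5,)

    def test_interval_order_violation(self):
        ds = SurvivalDataset.from_arrays(
            interval_left=[2.0, 0.0], interval_right=[1.0, np.inf],
            events=[1, 0], predictor=[0.0, 1.0],
        )
        assert any(v.code == "interval_order" for v in validate_dataset(ds).violations)

    def test_valid_dataset_passes(self, ph_dataset):
        assert validate_dataset(ph_dataset).ok

    def test_constant_predictor_flagged(self):
        ds = SurvivalDataset.from_arrays(times=[1, 2], events=[1, 1], predictor=[3.0, 3.0])
        assert any(
            v.code == "degenerate_predictor" for v in validate_dataset(ds).violations
        )


class TestSummarizeCovariate:
    def test_two_bins(self):
        ds = SurvivalDataset.from_arrays(times=[1, 1, 1], events=[1, 1, 1],
                                         predictor=[1.0, 2.0, 3.0])
        s = summarize_covariate(ds, "x", n_bins=2)
        assert s.median == 2.0
        assert [b[2] for b in s.histogram] == [1, 2]  # [1,2): 1, [2,3]: 2

    def test_constant_column_degenerate_bin(self):
        ds = SurvivalDataset.from_arrays(times=[1, 1, 1], events=[1, 1, 1],
                                         predictor=[5.0, 5.0, 5.0])
        s = summarize_covariate(ds, "x", n_bins=4)
        assert s.histogram == ((5.0, 5.0, 3),)
        assert s.median == 5.0

    def test_categorical_mode(self):
        ds = SurvivalDataset.from_arrays(
            times=[1, 2, 3], events=[1, 1, 1], predictor=[0.0, 1.0, 2.0],
            adjusters={"sex": np.array(["a", "a", "b"])},
            adjuster_kinds={"sex": "categorical"},
        )
        assert summarize_covariate(ds, "sex").mode == "a"

    @settings(deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(-50, 50), min_size=2, max_size=60),
        n_bins=st.integers(1, 25),
    )
    def test_histogram_counts_sum_to_non_missing(self, values, n_bins):
        ds = SurvivalDataset.from_arrays(
            times=np.ones(len(values)), events=np.ones(len(values), int),
            predictor=np.asarray(values),
        )
        s = summarize_covariate(ds, "x", n_bins=n_bins)
        assert sum(b[2] for b in s.histogram) == len(values) - s.n_missing
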