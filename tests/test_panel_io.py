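import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from healthdea import (
    BalanceError,
    GeneratorConfig,
    PanelDataset,
    PanelSchema,
    PositivityError,
    SchemaError,
    UnknownPeriodError,
    cross_section,
    generate_panel,
    read_panel,
    read_schema,
    write_panel,
)
from healthdea.panel_io import panels_equal


@pytest.fixture(scope="module")
def panel():
    return generate_panel(GeneratorConfig(n_dmus=5, periods=3, seed=9))[0]


def roundtrip(panel: PanelDataset) -> PanelDataset:
    buf = io.StringIO()
    write_panel(panel, buf)
    buf.seek(0)
    return read_panel(buf, panel.schema)


class TestRoundTrip:
    def test_identity_on_generator_output(self, panel):
        assert panels_equal(roundtrip(panel), panel)

    def test_column_order_follows_schema(self, panel):
        buf = io.StringIO()
        write_panel(panel, buf)
        header = buf.getvalue().splitlines()[0].split(",")
        sch = panel.schema
        assert header == [sch.dmu_column, sch.period_column, *sch.measure_names]

    def test_full_precision_serialisation(self, panel):
        # values like 1/3 must survive; no 3-dp display truncation on disk
        X = panel.X.copy()
        X[0, 0, 0] = 1.0 / 3.0
        p = PanelDataset(panel.dmus, panel.periods, X, panel.Y, panel.Z, panel.schema)
        assert roundtrip(p).X[0, 0, 0] == 1.0 / 3.0


class TestValidation:
    def test_minimal_panel(self):
        sch = PanelSchema(("x",), ("y",))
        df = "dmu,period,x,y\nA,1,1.0,2.0\n"
        p = read_panel(io.StringIO(df), sch)
        assert (p.n, p.T, p.schema.m, p.schema.s) == (1, 1, 1, 1)

    def test_missing_column_named(self):
        sch = PanelSchema(("x",), ("y",))
        with pytest.raises(SchemaError, match="y"):
            read_panel(io.StringIO("dmu,period,x\nA,1,1.0\n"), sch)

    def test_unbalanced_lists_gaps(self):
        sch = PanelSchema(("x",), ("y",))
        csv = "dmu,period,x,y\nA,1,1,1\nA,2,1,1\nB,1,1,1\n"
        with pytest.raises(BalanceError, match="B"):
            read_panel(io.StringIO(csv), sch)

    def test_zero_output_rejected(self):
        sch = PanelSchema(("x",), ("visits",))
        csv = "dmu,period,x,visits\nA,1,1,0.0\n"
        with pytest.raises(PositivityError, match="visits"):
            read_panel(io.StringIO(csv), sch)

    def test_nonconsecutive_periods_rejected(self):
        sch = PanelSchema(("x",), ("y",))
        csv = "dmu,period,x,y\nA,2010,1,1\nA,2012,1,1\n"
        with pytest.raises(BalanceError):
            read_panel(io.StringIO(csv), sch)

    def test_schema_role_overlap_rejected(self):
        with pytest.raises(SchemaError):
            PanelSchema(("x",), ("x",))

    def test_covariates_may_be_negative(self):
        sch = PanelSchema(("x",), ("y",), ("z",))
        csv = "dmu,period,x,y,z\nA,1,1,1,-5.0\n"
        assert read_panel(io.StringIO(csv), sch).Z[0, 0, 0] == -5.0


class TestCrossSection:
    def test_slice_matches_panel(self, panel):
        sec = cross_section(panel, panel.periods[-1])
        assert sec.dmus == panel.dmus
        np.testing.assert_array_equal(sec.X, panel.X[:, -1, :])
        np.testing.assert_array_equal(sec.Y, panel.Y[:, -1, :])

    def test_partition_restacks_to_panel(self, panel):
        X = np.stack([cross_section(panel, t).X for t in panel.periods], axis=1)
        Y = np.stack([cross_section(panel, t).Y for t in panel.periods], axis=1)
        np.testing.assert_array_equal(X, panel.X)
        np.testing.assert_array_equal(Y, panel.Y)

    def test_unknown_period(self, panel):
        with pytest.raises(UnknownPeriodError):
            cross_section(panel, panel.periods[0] - 1)


def test_read_schema_yaml(tmp_path):
    cfg = tmp_path / "schema.yaml"
    cfg.write_text(
        "inputs: [beds, staff]\noutputs: [visits]\ncovariates: [pgdp]\n"
        "dmu_column: city\nperiod_column: year\n"
    )
    sch = read_schema(cfg)
    assert sch.input_names == ("beds", "staff")
    assert sch.output_names == ("visits",)
    assert sch.dmu_column == "city"


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    n=st.integers(2, 4),
    T=st.integers(1, 3),
    corruption=st.sampled_from(["none", "zero_input", "negative_output", "drop_row"]),
    cell=st.integers(0, 10**6),
    data=st.data(),
)
def test_validation_accepts_exactly_the_valid_panels(n, T, corruption, cell, data):
    """Random panels pass iff uncorrupted; each corruption hits its own error."""
    sch = PanelSchema(("x1", "x2"), ("y1",))
    rows = []
    for i in range(n):
        for t in range(T):
            vals = [
                data.draw(st.floats(0.1, 100.0, allow_nan=False, allow_infinity=False))
                for _ in range(3)
            ]
            rows.append({"dmu": f"d{i}", "period": 2000 + t, "x1": vals[0], "x2": vals[1], "y1": vals[2]})
    df = pd.DataFrame(rows)
    r = cell % len(df)
    if corruption == "zero_input":
        df.loc[r, "x1"] = 0.0
    elif corruption == "negative_output":
        df.loc[r, "y1"] = -1.0
    elif corruption == "drop_row" and len(df) > 1:
        df = df.drop(index=r)

    buf = io.StringIO(df.to_csv(index=False))
    if corruption == "none" or (corruption == "drop_row" and T == 1):
        # dropping a DMU's only row removes the DMU entirely: still balanced
        p = read_panel(buf, sch)
        assert p.T == T and p.n in (n, n - 1)
        assert np.all(p.X > 0) and np.all(p.Y > 0)
        assert tuple(np.diff(p.periods)) == tuple([1] * (T - 1))
    elif corruption == "drop_row":
        with pytest.raises(BalanceError):
            read_panel(buf, sch)
    else:
        with pytest.raises(PositivityError):
            read_panel(buf, sch)
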