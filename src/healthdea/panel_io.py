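"""Role-tagged panel data: schema, container, CSV round trip and slicing.

A panel holds one row per (DMU, period) with named measure columns, each
assigned one of three roles: *input* (resources consumed — e.g. health
technicians, beds, total expenditure), *output* (services produced — visits,
discharges) or *covariate* (environmental factors used only in the
second-stage regression).  Efficiency scoring divides by inputs and outputs,
so those must be strictly positive; covariates may be any real number.

The panel must be balanced (no missing DMU-period cells) and the periods must
be consecutive integers, because the productivity index pairs adjacent
periods.  Missing data are rejected rather than imputed: callers drop
incomplete units before loading.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import (
    BalanceError,
    PositivityError,
    SchemaError,
    UnknownPeriodError,
)

__all__ = [
    "PanelSchema",
    "PanelDataset",
    "CrossSection",
    "read_panel",
    "write_panel",
    "cross_section",
    "read_schema",
]


@dataclass(frozen=True)
class PanelSchema:
    """Assignment of measure columns to roles.

    ``m = len(input_names)`` and ``s = len(output_names)`` are the input and
    output counts of every efficiency program built from the panel.
    """

    input_names: tuple[str, ...]
    output_names: tuple[str, ...]
    covariate_names: tuple[str, ...] = ()
    dmu_column: str = "dmu"
    period_column: str = "period"
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_names", tuple(self.input_names))
        object.__setattr__(self, "output_names", tuple(self.output_names))
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        if len(self.input_names) < 1:
            raise SchemaError("schema needs at least one input column")
        if len(self.output_names) < 1:
            raise SchemaError("schema needs at least one output column")
        roles = (
            list(self.input_names)
            + list(self.output_names)
            + list(self.covariate_names)
            + [self.dmu_column, self.period_column]
        )
        dupes = {name for name in roles if roles.count(name) > 1}
        if dupes:
            raise SchemaError(f"column names assigned to more than one role: {sorted(dupes)}")

    @property
    def m(self) -> int:
        return len(self.input_names)

    @property
    def s(self) -> int:
        return len(self.output_names)

    @property
    def p(self) -> int:
        return len(self.covariate_names)

    @property
    def measure_names(self) -> tuple[str, ...]:
        return self.input_names + self.output_names + self.covariate_names


@dataclass(frozen=True)
class PanelDataset:
    """Balanced DMU x period x measure panel.

    ``X`` (n, T, m) and ``Y`` (n, T, s) are strictly positive; ``Z`` (n, T, p)
    holds covariates and is unconstrained.  Periods are consecutive integers.
    """

    dmus: tuple[str, ...]
    periods: tuple[int, ...]
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    schema: PanelSchema

    def __post_init__(self) -> None:
        object.__setattr__(self, "dmus", tuple(self.dmus))
        object.__setattr__(self, "periods", tuple(int(t) for t in self.periods))
        for name in ("X", "Y", "Z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n, T = len(self.dmus), len(self.periods)
        expect = {"X": (n, T, self.schema.m), "Y": (n, T, self.schema.s), "Z": (n, T, self.schema.p)}
        for name, shape in expect.items():
            got = getattr(self, name).shape
            if got != shape:
                raise SchemaError(f"{name} has shape {got}, expected {shape}")
        diffs = np.diff(self.periods)
        if len(self.periods) > 1 and not np.all(diffs == 1):
            raise BalanceError(f"periods must be consecutive integers, got {self.periods}")
        for name, arr, cols in (
            ("input", self.X, self.schema.input_names),
            ("output", self.Y, self.schema.output_names),
        ):
            if not np.all(np.isfinite(arr)):
                raise PositivityError(f"non-finite {name} values present")
            if np.any(arr <= 0):
                i, t, j = map(int, np.argwhere(arr <= 0)[0])
                raise PositivityError(
                    f"nonpositive {name} '{cols[j]}' for DMU '{self.dmus[i]}' "
                    f"in period {self.periods[t]}: {arr[i, t, j]}"
                )
        if not np.all(np.isfinite(self.Z)):
            raise SchemaError("non-finite covariate values present")

    @property
    def n(self) -> int:
        return len(self.dmus)

    @property
    def T(self) -> int:
        return len(self.periods)

    def period_index(self, period: int) -> int:
        try:
            return self.periods.index(int(period))
        except ValueError:
            raise UnknownPeriodError(
                f"period {period} not in panel (periods {self.periods[0]}..{self.periods[-1]})"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame, one row per (dmu, period), columns in schema order."""
        sch = self.schema
        rows = []
        for i, d in enumerate(self.dmus):
            for t, per in enumerate(self.periods):
                row: dict[str, object] = {sch.dmu_column: d, sch.period_column: per}
                row.update(zip(sch.input_names, self.X[i, t]))
                row.update(zip(sch.output_names, self.Y[i, t]))
                row.update(zip(sch.covariate_names, self.Z[i, t]))
                rows.append(row)
        cols = [sch.dmu_column, sch.period_column, *sch.measure_names]
        return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class CrossSection:
    """All DMUs of one period: X (n, m) and Y (n, s), panel DMU order preserved."""

    period: int
    dmus: tuple[str, ...]
    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "dmus", tuple(self.dmus))
        object.__setattr__(self, "X", np.asarray(self.X, dtype=float))
        object.__setattr__(self, "Y", np.asarray(self.Y, dtype=float))
        if self.X.ndim != 2 or self.Y.ndim != 2 or self.X.shape[0] != self.Y.shape[0]:
            raise SchemaError("CrossSection X and Y must be 2-D with matching row counts")
        if np.any(self.X <= 0) or np.any(self.Y <= 0):
            raise PositivityError("cross-section inputs and outputs must be strictly positive")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def s(self) -> int:
        return self.Y.shape[1]


def _frame_to_panel(df: pd.DataFrame, schema: PanelSchema) -> PanelDataset:
    missing = [
        c
        for c in (schema.dmu_column, schema.period_column, *schema.measure_names)
        if c not in df.columns
    ]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    df = df.copy()
    try:
        df[schema.period_column] = df[schema.period_column].astype(int)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"period column '{schema.period_column}' must be integer-valued") from exc
    df = df.sort_values([schema.dmu_column, schema.period_column], kind="stable")

    dmus = tuple(dict.fromkeys(df[schema.dmu_column].astype(str)))
    periods = tuple(sorted(df[schema.period_column].unique()))
    key = list(zip(df[schema.dmu_column].astype(str), df[schema.period_column]))
    seen = set(key)
    if len(key) != len(seen):
        dupes = sorted({k for k in key if key.count(k) > 1})
        raise BalanceError(f"duplicate (dmu, period) rows: {dupes[:5]}")
    gaps = [(d, t) for d in dmus for t in periods if (d, t) not in seen]
    if gaps:
        raise BalanceError(f"panel is unbalanced; missing cells: {gaps[:10]}")

    n, T = len(dmus), len(periods)
    dmu_pos = {d: i for i, d in enumerate(dmus)}
    per_pos = {t: i for i, t in enumerate(periods)}

    def gather(names: tuple[str, ...]) -> np.ndarray:
        out = np.empty((n, T, len(names)))
        vals = df[list(names)].to_numpy(dtype=float) if names else np.empty((len(df), 0))
        for r, (d, t) in enumerate(key):
            out[dmu_pos[d], per_pos[t], :] = vals[r]
        return out

    return PanelDataset(
        dmus=dmus,
        periods=periods,
        X=gather(schema.input_names),
        Y=gather(schema.output_names),
        Z=gather(schema.covariate_names),
        schema=schema,
    )


def read_panel(source, schema: PanelSchema) -> PanelDataset:
    """Read a long-format CSV (one row per DMU-period) and validate it.

    ``source`` is a path or an open text/byte stream.  Raises
    :class:`SchemaError`, :class:`BalanceError` or :class:`PositivityError`
    with the offending columns/cells named.
    """
    df = pd.read_csv(source, float_precision="round_trip")
    return _frame_to_panel(df, schema)


def write_panel(panel: PanelDataset, sink) -> None:
    """Write the panel as long-format CSV with full float precision.

    ``read_panel(write_panel(p)) == p`` exactly: values are serialised with
    ``repr`` round-trip precision, never display-rounded.
    """
    df = panel.to_frame()
    df.to_csv(sink, index=False, float_format=lambda v: repr(float(v)))


def panels_equal(a: PanelDataset, b: PanelDataset) -> bool:
    """Exact equality of identifiers, schema roles and all numeric cells."""
    return (
        a.dmus == b.dmus
        and a.periods == b.periods
        and a.schema.measure_names == b.schema.measure_names
        and np.array_equal(a.X, b.X)
        and np.array_equal(a.Y, b.Y)
        and np.array_equal(a.Z, b.Z)
    )


def cross_section(panel: PanelDataset, period: int) -> CrossSection:
    """Slice one period out of the panel, preserving DMU order."""
    t = panel.period_index(period)
    return CrossSection(
        period=int(period), dmus=panel.dmus, X=panel.X[:, t, :], Y=panel.Y[:, t, :]
    )


def read_schema(source) -> PanelSchema:
    """Load a schema from a YAML key/value config.

    Expected keys: ``inputs``, ``outputs`` (lists), optional ``covariates``,
    ``dmu_column``, ``period_column``, ``units``.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "read"):
        raw = source.read() if hasattr(source, "read") else open(source).read()
    else:
        raw = open(source).read()
    cfg = yaml.safe_load(io.StringIO(raw if isinstance(raw, str) else raw.decode()))
    if not isinstance(cfg, dict) or "inputs" not in cfg or "outputs" not in cfg:
        raise SchemaError("schema config must be a mapping with 'inputs' and 'outputs' lists")
    return PanelSchema(
        input_names=tuple(cfg["inputs"]),
        output_names=tuple(cfg["outputs"]),
        covariate_names=tuple(cfg.get("covariates", ())),
        dmu_column=cfg.get("dmu_column", "dmu"),
        period_column=cfg.get("period_column", "period"),
        units=dict(cfg.get("units", {})),
    )


def with_measure_scaled(panel: PanelDataset, name: str, factor: float) -> PanelDataset:
    """Rescale one measure column everywhere (a unit change). Test/analysis helper."""
    sch = panel.schema
    X, Y, Z = panel.X.copy(), panel.Y.copy(), panel.Z.copy()
    if name in sch.input_names:
        X[:, :, sch.input_names.index(name)] *= factor
    elif name in sch.output_names:
        Y[:, :, sch.output_names.index(name)] *= factor
    elif name in sch.covariate_names:
        Z[:, :, sch.covariate_names.index(name)] *= factor
    else:
        raise SchemaError(f"unknown measure column '{name}'")
    return replace(panel, X=X, Y=Y, Z=Z)
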