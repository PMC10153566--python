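"""Adjacent-period Malmquist total-factor-productivity index and decomposition.

For each DMU and adjacent period pair (t, t+1) six radial distance-function
values are computed: four CRS efficiencies (each period's data against each
period's frontier) and two within-period VRS efficiencies.  Writing
E^f_d for the CRS Farrell efficiency of period-d data on the period-f
frontier, the standard decomposition is

    EFFCH  = E^{t+1}_{t+1} / E^t_t                     (catch-up)
    TECHCH = sqrt( (E^t_{t+1}/E^{t+1}_{t+1}) * (E^t_t/E^{t+1}_t) )
                                                       (frontier shift)
    PECH   = V^{t+1}_{t+1} / V^t_t                     (VRS catch-up)
    SECH   = EFFCH / PECH                              (scale efficiency)
    TFPCH  = EFFCH * TECHCH

so TFPCH = EFFCH*TECHCH and EFFCH = PECH*SECH hold to machine precision by
construction.  TFPCH > 1 means productivity rose between t and t+1.

Summaries are geometric means (the convention of the DEAP software): the
multiplicative identities then survive averaging, and the grand mean equals
the geometric mean of the per-pair means on balanced record sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SolverError
from .panel_io import PanelDataset, cross_section
from .radial_dea import RTS, DistanceSpec, Orientation, radial_distance

__all__ = [
    "MalmquistRecord",
    "MalmquistSummary",
    "malmquist_record",
    "malmquist_records",
    "summarize_malmquist",
    "INDEX_NAMES",
]

INDEX_NAMES = ("EFFCH", "TECHCH", "PECH", "SECH", "TFPCH")


@dataclass(frozen=True)
class MalmquistRecord:
    dmu: str
    period_pair: tuple[int, int]
    EFFCH: float
    TECHCH: float
    PECH: float
    SECH: float
    TFPCH: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


def _efficiency(x, y, section, orientation, rts) -> float:
    score = radial_distance(x, y, section, DistanceSpec(orientation=orientation, rts=rts))
    if not score.optimal:
        raise SolverError(
            f"distance LP not optimal (status={score.status}); cannot form Malmquist record"
        )
    return score.efficiency


def malmquist_record(
    dmu: str,
    t: int,
    panel: PanelDataset,
    orientation: Orientation = Orientation.OUTPUT,
) -> MalmquistRecord:
    """Index record for one DMU between periods ``t`` and ``t+1``."""
    i = panel.dmus.index(dmu)
    it = panel.period_index(t)
    panel.period_index(t + 1)  # validates
    sec_t = cross_section(panel, t)
    sec_t1 = cross_section(panel, t + 1)
    x_t, y_t = panel.X[i, it], panel.Y[i, it]
    x_t1, y_t1 = panel.X[i, it + 1], panel.Y[i, it + 1]

    e_t_t = _efficiency(x_t, y_t, sec_t, orientation, RTS.CRS)
    e_t1_t1 = _efficiency(x_t1, y_t1, sec_t1, orientation, RTS.CRS)
    e_t_t1 = _efficiency(x_t1, y_t1, sec_t, orientation, RTS.CRS)  # period t+1 data, frontier t
    e_t1_t = _efficiency(x_t, y_t, sec_t1, orientation, RTS.CRS)  # period t data, frontier t+1
    v_t_t = _efficiency(x_t, y_t, sec_t, orientation, RTS.VRS)
    v_t1_t1 = _efficiency(x_t1, y_t1, sec_t1, orientation, RTS.VRS)

    effch = e_t1_t1 / e_t_t
    techch = float(np.sqrt((e_t_t1 / e_t1_t1) * (e_t_t / e_t1_t)))
    pech = v_t1_t1 / v_t_t
    sech = effch / pech
    tfpch = effch * techch
    return MalmquistRecord(
        dmu=dmu,
        period_pair=(int(t), int(t) + 1),
        EFFCH=effch,
        TECHCH=techch,
        PECH=pech,
        SECH=sech,
        TFPCH=tfpch,
    )


def malmquist_records(
    panel: PanelDataset, orientation: Orientation = Orientation.OUTPUT
) -> list[MalmquistRecord]:
    """All DMU x adjacent-period records of the panel."""
    return [
        malmquist_record(dmu, t, panel, orientation)
        for dmu in panel.dmus
        for t in panel.periods[:-1]
    ]


def _geomean(values: np.ndarray, axis=None) -> np.ndarray:
    return np.exp(np.mean(np.log(values), axis=axis))


@dataclass(frozen=True)
class MalmquistSummary:
    """Geometric-mean summaries of a balanced record set.

    ``by_pair``: period-pair rows x five index columns (geometric mean over
    DMUs); ``by_dmu``: DMU rows (geometric mean over pairs); ``grand``: the
    overall geometric means.  Render at 3 decimals for reporting.
    """

    by_pair: pd.DataFrame
    by_dmu: pd.DataFrame
    grand: pd.Series

    def to_frame(self, decimals: int | None = 3) -> pd.DataFrame:
        out = pd.concat([self.by_pair, self.grand.to_frame("Mean").T])
        return out if decimals is None else out.round(decimals)


def summarize_malmquist(records: list[MalmquistRecord]) -> MalmquistSummary:
    """Geometric means per period pair, per DMU, and overall.

    Requires a balanced set (every DMU appears for every period pair);
    raises ``ValueError`` listing missing cells otherwise.
    """
    if not records:
        raise ValueError("no records to summarise")
    dmus = list(dict.fromkeys(r.dmu for r in records))
    pairs = sorted({r.period_pair for r in records})
    seen = {(r.dmu, r.period_pair) for r in records}
    missing = [(d, p) for d in dmus for p in pairs if (d, p) not in seen]
    if missing or len(records) != len(dmus) * len(pairs):
        raise ValueError(f"record set is not balanced; missing cells: {missing[:10]}")

    cube = np.empty((len(dmus), len(pairs), len(INDEX_NAMES)))
    dpos = {d: i for i, d in enumerate(dmus)}
    ppos = {p: j for j, p in enumerate(pairs)}
    for r in records:
        cube[dpos[r.dmu], ppos[r.period_pair]] = [getattr(r, n) for n in INDEX_NAMES]

    pair_labels = [f"{a}-{b}" for a, b in pairs]
    by_pair = pd.DataFrame(_geomean(cube, axis=0), index=pair_labels, columns=INDEX_NAMES)
    by_dmu = pd.DataFrame(_geomean(cube, axis=1), index=dmus, columns=INDEX_NAMES)
    grand = pd.Series(_geomean(cube.reshape(-1, len(INDEX_NAMES)), axis=0), index=INDEX_NAMES)
    return MalmquistSummary(by_pair=by_pair, by_dmu=by_dmu, grand=grand)
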