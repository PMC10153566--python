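"""Non-oriented SBM and super-efficiency SBM scoring.

The slacks-based measure (SBM) scores a decision-making unit (DMU) k against
the envelopment of a cross-section by minimising

    rho = (1 - (1/m) sum_a s_a^-/x_ak) / (1 + (1/s) sum_c s_c^+/y_ck)

subject to  X'lam + s^- = x_k,  Y'lam - s^+ = y_k,  lam, s^-, s^+ >= 0
(and sum(lam) = 1 under variable returns to scale).  rho is in (0, 1] and
equals 1 exactly when no slack exists, i.e. the DMU is on the frontier.

Frontier DMUs are then ranked with the super-efficiency SBM: the DMU is
removed from the reference set and the score

    delta = ((1/m) sum_a xbar_a/x_ak) / ((1/s) sum_c ybar_c/y_ck)  >= 1

is minimised over projection points (xbar >= x_k, 0 < ybar <= y_k) that the
remaining DMUs can weakly dominate.  Both fractional programs are linearised
by the Charnes-Cooper transformation (scale every variable by t > 0 and pin
the denominator to 1), solved with HiGHS, and de-scaled.

The combined score reported per DMU-period is rho for sub-frontier DMUs and
delta for frontier DMUs, so efficient units can be ranked above 1 while
inefficient units keep their slack-based score below 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .errors import SolverError
from .panel_io import CrossSection, PanelDataset, cross_section
from .radial_dea import RTS

__all__ = [
    "SBMResult",
    "SuperSBMResult",
    "ScoreMatrix",
    "ProjectionReport",
    "EFFICIENCY_THRESHOLD",
    "sbm_score",
    "super_sbm_score",
    "combined_score",
    "score_matrix",
    "projection_report",
]

#: A DMU is routed to the super-efficiency model when rho >= 1 - this.
EFFICIENCY_THRESHOLD = 1e-6


@dataclass(frozen=True)
class SBMResult:
    rho: float
    input_slacks: np.ndarray  # (m,) input excess s^-
    output_slacks: np.ndarray  # (s,) output shortfall s^+
    lambdas: np.ndarray  # (n,) reference weights
    status: str  # "optimal" | "error"

    @property
    def efficient(self) -> bool:
        return self.status == "optimal" and self.rho >= 1.0 - EFFICIENCY_THRESHOLD


@dataclass(frozen=True)
class SuperSBMResult:
    delta: float | None
    projection_inputs: np.ndarray | None  # xbar >= x_k
    projection_outputs: np.ndarray | None  # 0 < ybar <= y_k
    lambdas: np.ndarray | None  # weights over the other n-1 DMUs
    status: str  # "optimal" | "infeasible"


def _solve_lp(c, A_ub, b_ub, A_eq, b_eq, n_vars):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=[(0, None)] * n_vars,
        method="highs",
    )
    return res


def sbm_score(k: int, section: CrossSection, rts: RTS = RTS.VRS) -> SBMResult:
    """Non-oriented SBM efficiency of DMU ``k`` within ``section``.

    Solved as a single LP via the Charnes-Cooper transformation: with
    variables (t, L = t*lam, S- = t*s^-, S+ = t*s^+),

        min  t - (1/m) sum_a S_a^-/x_ak
        s.t. t + (1/s) sum_c S_c^+/y_ck = 1
             t*x_k = X'L + S-,   t*y_k = Y'L - S+
             sum(L) = t (VRS),   all variables >= 0.
    """
    X, Y = section.X, section.Y
    n, m = X.shape
    s = Y.shape[1]
    xk, yk = X[k], Y[k]

    # variable order: [t, L (n), S- (m), S+ (s)]
    nv = 1 + n + m + s
    c = np.zeros(nv)
    c[0] = 1.0
    c[1 + n : 1 + n + m] = -1.0 / (m * xk)

    rows = []
    rhs = []
    # denominator normalisation: t + (1/s) sum S+/y = 1
    row = np.zeros(nv)
    row[0] = 1.0
    row[1 + n + m :] = 1.0 / (s * yk)
    rows.append(row)
    rhs.append(1.0)
    # input balance: X'L + S- - t*x_k = 0
    for a in range(m):
        row = np.zeros(nv)
        row[0] = -xk[a]
        row[1 : 1 + n] = X[:, a]
        row[1 + n + a] = 1.0
        rows.append(row)
        rhs.append(0.0)
    # output balance: Y'L - S+ - t*y_k = 0
    for cc in range(s):
        row = np.zeros(nv)
        row[0] = -yk[cc]
        row[1 : 1 + n] = Y[:, cc]
        row[1 + n + m + cc] = -1.0
        rows.append(row)
        rhs.append(0.0)
    if rts is RTS.VRS:
        row = np.zeros(nv)
        row[0] = -1.0
        row[1 : 1 + n] = 1.0
        rows.append(row)
        rhs.append(0.0)

    res = _solve_lp(c, None, None, np.array(rows), np.array(rhs), nv)
    if not res.success:
        return SBMResult(np.nan, np.full(m, np.nan), np.full(s, np.nan), np.full(n, np.nan), "error")

    t = float(res.x[0])
    if t <= 1e-12:
        raise SolverError("Charnes-Cooper scale collapsed to zero in SBM")
    lam = res.x[1 : 1 + n] / t
    s_minus = res.x[1 + n : 1 + n + m] / t
    s_plus = res.x[1 + n + m :] / t
    rho = float(res.fun)
    return SBMResult(rho=rho, input_slacks=s_minus, output_slacks=s_plus, lambdas=lam, status="optimal")


def super_sbm_score(k: int, section: CrossSection, rts: RTS = RTS.VRS) -> SuperSBMResult:
    """Super-efficiency SBM of frontier DMU ``k`` (reference set excludes k).

    Linearised with variables (t, L, Xbar = t*xbar, Ybar = t*ybar):

        min  (1/m) sum_a Xbar_a/x_ak
        s.t. (1/s) sum_c Ybar_c/y_ck = 1
             Xbar >= X_{-k}'L,  Ybar <= Y_{-k}'L
             Xbar >= t*x_k,     Ybar <= t*y_k
             sum(L) = t (VRS),  all variables >= 0.

    delta >= 1 by construction; callers should only invoke this for DMUs with
    SBM rho >= 1 - EFFICIENCY_THRESHOLD.
    """
    X, Y = section.X, section.Y
    n, m = X.shape
    s = Y.shape[1]
    if n < 2:
        return SuperSBMResult(None, None, None, None, "infeasible")
    xk, yk = X[k], Y[k]
    others = [b for b in range(n) if b != k]
    Xo, Yo = X[others], Y[others]  # (n-1, m), (n-1, s)
    no = n - 1

    # variable order: [t, L (n-1), Xbar (m), Ybar (s)]
    nv = 1 + no + m + s
    c = np.zeros(nv)
    c[1 + no : 1 + no + m] = 1.0 / (m * xk)

    eq_rows, eq_rhs = [], []
    row = np.zeros(nv)
    row[1 + no + m :] = 1.0 / (s * yk)
    eq_rows.append(row)
    eq_rhs.append(1.0)
    if rts is RTS.VRS:
        row = np.zeros(nv)
        row[0] = -1.0
        row[1 : 1 + no] = 1.0
        eq_rows.append(row)
        eq_rhs.append(0.0)

    ub_rows, ub_rhs = [], []
    # X_{-k}'L - Xbar <= 0
    for a in range(m):
        row = np.zeros(nv)
        row[1 : 1 + no] = Xo[:, a]
        row[1 + no + a] = -1.0
        ub_rows.append(row)
        ub_rhs.append(0.0)
    # Ybar - Y_{-k}'L <= 0
    for cc in range(s):
        row = np.zeros(nv)
        row[1 : 1 + no] = -Yo[:, cc]
        row[1 + no + m + cc] = 1.0
        ub_rows.append(row)
        ub_rhs.append(0.0)
    # t*x_k - Xbar <= 0
    for a in range(m):
        row = np.zeros(nv)
        row[0] = xk[a]
        row[1 + no + a] = -1.0
        ub_rows.append(row)
        ub_rhs.append(0.0)
    # Ybar - t*y_k <= 0
    for cc in range(s):
        row = np.zeros(nv)
        row[0] = -yk[cc]
        row[1 + no + m + cc] = 1.0
        ub_rows.append(row)
        ub_rhs.append(0.0)

    res = _solve_lp(c, np.array(ub_rows), np.array(ub_rhs), np.array(eq_rows), np.array(eq_rhs), nv)
    if res.status == 2:
        return SuperSBMResult(None, None, None, None, "infeasible")
    if not res.success:
        raise SolverError(f"super-SBM LP failed: {res.message}")

    t = float(res.x[0])
    if t <= 1e-12:
        raise SolverError("Charnes-Cooper scale collapsed to zero in super-SBM")
    lam = res.x[1 : 1 + no] / t
    xbar = res.x[1 + no : 1 + no + m] / t
    ybar = res.x[1 + no + m :] / t
    return SuperSBMResult(
        delta=float(res.fun),
        projection_inputs=xbar,
        projection_outputs=ybar,
        lambdas=lam,
        status="optimal",
    )


def combined_score(
    k: int, section: CrossSection, rts: RTS = RTS.VRS, infeasible_policy: str = "omit"
) -> tuple[float | None, str]:
    """SBM rho for sub-frontier DMUs, super-efficiency delta for frontier DMUs.

    Returns ``(score, flag)`` where flag is ``"sbm"``, ``"super"``,
    ``"infeasible"`` or ``"error"``.  An infeasible super score is omitted
    (score ``None``) under the default policy, or clamped to 1.0 with
    ``infeasible_policy="clamp"``; a warning is logged either way.
    """
    if infeasible_policy not in ("omit", "clamp"):
        raise ValueError("infeasible_policy must be 'omit' or 'clamp'")
    base = sbm_score(k, section, rts)
    if base.status != "optimal":
        return None, "error"
    if not base.efficient:
        return base.rho, "sbm"
    sup = super_sbm_score(k, section, rts)
    if sup.status != "optimal":
        warnings.warn(
            f"super-efficiency SBM infeasible for DMU index {k} in period "
            f"{section.period}; score {'clamped to 1.0' if infeasible_policy == 'clamp' else 'omitted'}",
            stacklevel=2,
        )
        return (1.0, "infeasible") if infeasible_policy == "clamp" else (None, "infeasible")
    return sup.delta, "super"


@dataclass(frozen=True)
class ScoreMatrix:
    """Combined scores per DMU (rows) and period (columns) with means.

    Means are arithmetic, computed over available cells at full precision;
    rounding to 3 decimals happens only when rendering.
    """

    dmus: tuple[str, ...]
    periods: tuple[int, ...]
    scores: np.ndarray  # (n, T), NaN where absent
    flags: np.ndarray  # (n, T) object array of status strings

    @classmethod
    def from_scores(cls, scores, dmus, periods, flags=None) -> "ScoreMatrix":
        scores = np.asarray(scores, dtype=float)
        if flags is None:
            flags = np.where(np.isnan(scores), "absent", "ok").astype(object)
        return cls(tuple(dmus), tuple(int(t) for t in periods), scores, np.asarray(flags, dtype=object))

    @property
    def dmu_means(self) -> np.ndarray:
        return np.nanmean(self.scores, axis=1)

    @property
    def period_means(self) -> np.ndarray:
        return np.nanmean(self.scores, axis=0)

    @property
    def grand_mean(self) -> float:
        return float(np.nanmean(self.scores))

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        """Tabular layout: DMU rows, period columns, plus Mean row and column."""
        body = np.c_[self.scores, self.dmu_means]
        mean_row = np.r_[self.period_means, self.grand_mean]
        data = np.vstack([body, mean_row])
        if decimals is not None:
            data = np.round(data, decimals)
        return pd.DataFrame(
            data,
            index=[*self.dmus, "Mean"],
            columns=[*(str(t) for t in self.periods), "Mean"],
        )


def score_matrix(panel: PanelDataset, rts: RTS = RTS.VRS) -> ScoreMatrix:
    """Combined score for every DMU-period cell of the panel."""
    n, T = panel.n, panel.T
    scores = np.full((n, T), np.nan)
    flags = np.empty((n, T), dtype=object)
    for t, period in enumerate(panel.periods):
        section = cross_section(panel, period)
        for k in range(n):
            val, flag = combined_score(k, section, rts)
            flags[k, t] = flag
            if val is not None:
                scores[k, t] = val
    if np.isnan(scores).any():
        warnings.warn("some DMU-period scores are absent; means use available cells", stacklevel=2)
    return ScoreMatrix(panel.dmus, panel.periods, scores, flags)


@dataclass(frozen=True)
class ProjectionReport:
    """Input redundancy / output shortage for sub-frontier DMUs of one period.

    Amounts are the optimal SBM slacks in the measure's own units;
    percentages are slack / observed x 100 (inputs strictly below 100%).
    """

    period: int
    table: pd.DataFrame  # rows: sub-frontier DMUs; columns: per measure amount + pct

    def rounded(self, decimals: int = 2) -> pd.DataFrame:
        out = self.table.copy()
        pct_cols = [c for c in out.columns if c.endswith("_pct")]
        out[pct_cols] = out[pct_cols].round(decimals)
        return out


def projection_report(panel: PanelDataset, period: int, rts: RTS = RTS.VRS) -> ProjectionReport:
    """Slack projection for every DMU scoring below 1 in ``period``."""
    section = cross_section(panel, period)
    sch = panel.schema
    rows = []
    for k in range(panel.n):
        base = sbm_score(k, section, rts)
        if base.status != "optimal" or base.efficient:
            continue
        row: dict[str, float | str] = {"dmu": panel.dmus[k], "score": base.rho}
        for a, name in enumerate(sch.input_names):
            amt = float(base.input_slacks[a])
            row[f"{name}_redundancy"] = amt
            row[f"{name}_pct"] = amt / section.X[k, a] * 100.0
        for c, name in enumerate(sch.output_names):
            amt = float(base.output_slacks[c])
            row[f"{name}_shortage"] = amt
            row[f"{name}_pct"] = amt / section.Y[k, c] * 100.0
        rows.append(row)
    cols = ["dmu", "score"]
    for name in sch.input_names:
        cols += [f"{name}_redundancy", f"{name}_pct"]
    for name in sch.output_names:
        cols += [f"{name}_shortage", f"{name}_pct"]
    table = pd.DataFrame(rows, columns=cols).set_index("dmu")
    return ProjectionReport(period=int(period), table=table)
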