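"""Radial envelopment LPs: within- and cross-period distance functions.

These are the Farrell/Shephard distance functions that feed the Malmquist
productivity index.  Output orientation solves

    max phi  s.t.  X'lam <= x,  Y'lam >= phi*y,  lam >= 0  (+ sum(lam)=1 VRS)

and reports Farrell efficiency 1/phi; input orientation solves the symmetric
``min theta`` program and reports theta.  The ``distance`` field always uses
the Shephard convention (output distance = 1/phi <= 1 within-period; input
distance = 1/theta >= 1), so Malmquist ratios are orientation-consistent.

Within a period every efficiency is <= 1; against another period's frontier
it may exceed 1.  Cross-period CRS programs are always feasible for positive
data; cross-period VRS programs can be infeasible and are reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import linprog

from .errors import SolverError
from .panel_io import CrossSection

__all__ = ["Orientation", "RTS", "DistanceSpec", "RadialScore", "radial_distance"]

_FEAS_TOL = 1e-9


class Orientation(str, Enum):
    INPUT = "input"
    OUTPUT = "output"


class RTS(str, Enum):
    CRS = "crs"
    VRS = "vrs"


@dataclass(frozen=True)
class DistanceSpec:
    orientation: Orientation = Orientation.OUTPUT
    rts: RTS = RTS.CRS


@dataclass(frozen=True)
class RadialScore:
    """Result of one radial LP.

    ``efficiency`` is the Farrell measure (theta for input orientation,
    1/phi for output); ``distance`` the Shephard value.  ``lambdas`` is any
    optimal reference weight vector (degenerate optima allowed); only the
    optimal value feeds downstream indices.
    """

    efficiency: float | None
    distance: float | None
    lambdas: np.ndarray | None
    status: str  # "optimal" | "infeasible"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def radial_distance(
    x: np.ndarray, y: np.ndarray, reference: CrossSection, spec: DistanceSpec
) -> RadialScore:
    """Distance of the point (x, y) to the frontier spanned by ``reference``."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("evaluated point must be strictly positive")
    X, Y = reference.X, reference.Y  # (n, m), (n, s)
    n, m = X.shape
    s = Y.shape[1]
    if x.shape != (m,) or y.shape != (s,):
        raise ValueError("point dimensions do not match reference section")

    # variables: [scale (phi or theta), lam_1..lam_n]
    if spec.orientation is Orientation.OUTPUT:
        c = np.r_[-1.0, np.zeros(n)]  # max phi
        A_ub = np.block(
            [
                [np.zeros((m, 1)), X.T],  # X'lam <= x
                [y[:, None], -Y.T],  # phi*y - Y'lam <= 0
            ]
        )
        b_ub = np.r_[x, np.zeros(s)]
    else:
        c = np.r_[1.0, np.zeros(n)]  # min theta
        A_ub = np.block(
            [
                [-x[:, None], X.T],  # X'lam - theta*x <= 0
                [np.zeros((s, 1)), -Y.T],  # Y'lam >= y
            ]
        )
        b_ub = np.r_[np.zeros(m), -y]

    A_eq = b_eq = None
    if spec.rts is RTS.VRS:
        A_eq = np.r_[0.0, np.ones(n)][None, :]
        b_eq = np.array([1.0])

    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=[(0, None)] * (1 + n),
        method="highs",
    )
    if res.status == 2:  # infeasible
        return RadialScore(None, None, None, "infeasible")
    if not res.success:
        raise SolverError(f"radial LP failed: {res.message}")

    scale = float(res.x[0])
    lam = np.asarray(res.x[1:])
    if spec.orientation is Orientation.OUTPUT:
        if scale <= _FEAS_TOL:
            raise SolverError("degenerate output expansion phi ~ 0")
        eff = 1.0 / scale
        dist = 1.0 / scale
    else:
        eff = scale
        dist = 1.0 / scale if scale > _FEAS_TOL else float("inf")
    return RadialScore(efficiency=eff, distance=dist, lambdas=lam, status="optimal")
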