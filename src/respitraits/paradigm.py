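"""Classical whole-plant respiration models in closed form.

Three formalisms are covered:

* the growth-and-maintenance decomposition R = gR * dW/dt + mR * W, with the
  growth coefficient gR (mol CO2 released per mol C incorporated) and the
  maintenance coefficient mR (mol CO2 per mol biomass C per unit time);
* its generalization R = sum_r alpha_r * v_r over arbitrary process rates
  with unit CO2 costs;
* a nitrogen-driven growth balance in which protein N sustains carbon gain,
  dW/dt = (phiCN*Np/k - phiCN*gamma*W - mR*W) / (1 + gR), a linear ODE
  dW/dt = a - b*W with a known exponential solution; and
* the steady-state leaf photosynthesis fluxes A = Vc - 0.5*Vo - Rd of the
  Farquhar-von Caemmerer-Berry (FvCB) model, with the derived carbon use
  efficiency CUE = 1 - (0.5*Vo + Rd)/Vc.

Time and amount units are caller-defined but must be consistent; trajectory
outputs echo the configured unit label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class GrowthMaintenanceParams:
    gR: float  # growth respiration coefficient, mol CO2 / mol C
    mR: float  # maintenance respiration coefficient, mol CO2 / (mol C * time)

    def __post_init__(self) -> None:
        if self.gR < 0 or self.mR < 0:
            raise ValueError("gR and mR must be nonnegative")


def respiration_eq1(params: GrowthMaintenanceParams, dWdt: float,
                    W: float) -> tuple[float, float, float]:
    """Total, growth and maintenance respiration for a growth rate and biomass.

    Returns (R, R_growth, R_maintenance) with R = gR*dWdt + mR*W.
    """
    if W < 0:
        raise ValueError("biomass W must be nonnegative")
    r_growth = params.gR * dWdt
    r_maint = params.mR * W
    return r_growth + r_maint, r_growth, r_maint


@dataclass
class UnitCostSpec:
    """Per-process CO2 costs alpha_r and process rates v_r."""

    costs: dict[str, float]
    rates: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(self.rates) - set(self.costs)
        if missing:
            raise ValueError(f"rates given for processes without costs: {sorted(missing)}")
        for pid, alpha in self.costs.items():
            if alpha < 0:
                logger.warning("process %s has negative CO2 cost %g "
                               "(CO2-consuming process)", pid, alpha)


def respiration_general(spec: UnitCostSpec) -> float:
    """R = sum over processes of alpha_r * v_r; absent rates contribute 0."""
    return sum(spec.costs[pid] * rate for pid, rate in spec.rates.items())


@dataclass
class NCGrowthParams:
    phiCN: float  # nitrogen-to-carbon conversion factor
    Np: float     # protein nitrogen pool
    gamma: float  # structural N per C
    k: float      # carbon-to-biomass proportionality (W = k*C)
    W0: float     # initial biomass, mol C

    def __post_init__(self) -> None:
        if min(self.phiCN, self.Np, self.gamma, self.W0) < 0 or self.k <= 0:
            raise ValueError("parameters must be nonnegative with k > 0")


@dataclass
class GrowthTrajectory:
    t: np.ndarray
    W: np.ndarray
    dWdt: np.ndarray
    R: np.ndarray
    a: float
    b: float
    time_unit: str = "arbitrary"

    def closed_form(self) -> np.ndarray:
        """W(t) = a/b + (W0 - a/b) * exp(-b t) (or W0 + a t when b = 0)."""
        if self.b == 0:
            return self.W[0] + self.a * self.t
        wss = self.a / self.b
        return wss + (self.W[0] - wss) * np.exp(-self.b * self.t)


def simulate_nc_growth(gm: GrowthMaintenanceParams, nc: NCGrowthParams,
                       t_grid, time_unit: str = "arbitrary",
                       rtol: float = 1e-8) -> GrowthTrajectory:
    """Integrate the nitrogen-carbon growth balance dW/dt = a - b*W.

    a = phiCN*Np / (k*(1+gR)) and b = (phiCN*gamma + mR)/(1+gR).  A fixed-step
    4th-order Runge-Kutta scheme is used, halving the step until the solution
    matches the closed form within *rtol* relative error; the system is linear
    and non-stiff, so this always terminates quickly.  Respiration along the
    trajectory follows the growth-and-maintenance decomposition.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0) or t[0] != 0:
        raise ValueError("t_grid must be increasing with t[0] = 0")
    a = nc.phiCN * nc.Np / (nc.k * (1.0 + gm.gR))
    b = (nc.phiCN * nc.gamma + gm.mR) / (1.0 + gm.gR)

    def rhs(w: float) -> float:
        return a - b * w

    def closed(ts: np.ndarray) -> np.ndarray:
        if b == 0:
            return nc.W0 + a * ts
        wss = a / b
        return wss + (nc.W0 - wss) * np.exp(-b * ts)

    substeps = 1
    while True:
        W = np.empty_like(t)
        W[0] = nc.W0
        for i in range(len(t) - 1):
            h = (t[i + 1] - t[i]) / substeps
            w = W[i]
            for _ in range(substeps):
                k1 = rhs(w)
                k2 = rhs(w + 0.5 * h * k1)
                k3 = rhs(w + 0.5 * h * k2)
                k4 = rhs(w + h * k3)
                w = w + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            W[i + 1] = w
        ref = closed(t)
        scale = np.maximum(np.abs(ref), 1e-300)
        if np.max(np.abs(W - ref) / scale) <= rtol or substeps >= 2 ** 16:
            break
        substeps *= 2

    dWdt = a - b * W
    R = gm.gR * dWdt + gm.mR * W
    return GrowthTrajectory(t=t, W=W, dWdt=dWdt, R=R, a=a, b=b, time_unit=time_unit)


@dataclass
class FvCBFluxes:
    """RuBisCO carboxylation (Vc), oxygenation (Vo) and day respiration (Rd)."""

    Vc: float
    Vo: float
    Rd: float

    def __post_init__(self) -> None:
        if self.Vc < 0 or self.Vo < 0 or self.Rd < 0:
            raise ValueError("FvCB fluxes must be nonnegative")


def fvcb_assimilation(f: FvCBFluxes) -> float:
    """Net CO2 assimilation A = Vc - 0.5*Vo - Rd."""
    return f.Vc - 0.5 * f.Vo - f.Rd


def cue_from_fvcb(f: FvCBFluxes) -> float:
    """Carbon use efficiency 1 - (0.5*Vo + Rd)/Vc; equals A/Vc.

    Raises ValueError when Vc = 0 (no gross carboxylation to be efficient
    with).
    """
    if f.Vc == 0:
        raise ValueError("CUE undefined: Vc = 0")
    return 1.0 - (0.5 * f.Vo + f.Rd) / f.Vc


def rd_from_assimilation(A: float, Vc: float, Vo: float) -> float:
    """Invert the FvCB balance: Rd = Vc - 0.5*Vo - A."""
    return Vc - 0.5 * Vo - A
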