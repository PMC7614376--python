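"""Single-cell excitable dynamics: FitzHugh–Nagumo and Sherman–Rinzel–Keizer.

Two node models are supported.  The FitzHugh–Nagumo (FHN) model is the
minimal two-variable caricature of an excitable unit:

    dV/dt = V - V^3/3 - W + G*I - I_coup
    tau dW/dt = V + a - b*W

where the usual stimulus current has been split into a node-intrinsic
excitability ``I`` and a network-wide drive ``G`` in [0, 1].

The Sherman–Rinzel–Keizer (SRK) model is a three-variable pancreatic
beta-cell burster (membrane voltage V, delayed-rectifier activation n,
cytosolic calcium c) driven by K+, Ca2+, Ca2+-activated K+ and leak
currents.  The leak current carries the glucose dependence,

    I_L = g_L * (1 - G) * (V - V_K),

so the cell's excitability is set jointly by the leak conductance g_L
(cell-intrinsic) and the glucose drive G (global): raising either G or
lowering g_L pushes the cell across a Hopf bifurcation from quiescence
into bursting.  The Hopf locus is the level set (1 - G) * g_L = const.

Both models expose a right-hand side, an analytic Jacobian of the
single-cell subsystem, and Hopf-point detection used to parametrise
"excitability" throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "FHNParams",
    "SRKParams",
    "HopfPoint",
    "NoHopfInRange",
    "fhn_rhs",
    "fhn_jacobian",
    "srk_gating_steady",
    "srk_tau_n",
    "srk_currents",
    "srk_rhs",
    "srk_jacobian",
    "srk_equilibrium",
    "fhn_equilibrium",
    "find_hopf_fhn",
    "find_hopf_fhn_eigen",
    "find_hopf_srk",
    "simulate_single_cell",
]


@dataclass
class FHNParams:
    """FitzHugh–Nagumo parameters (dimensionless).

    ``I`` is the node's maximum stimulus current (its excitability) and
    ``G`` in [0, 1] is the shared network drive; the effective stimulus
    is the product ``G * I``.
    """

    a: float = 0.7
    b: float = 0.8
    tau: float = 12.5
    I: float = 1.0
    G: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not 0.0 <= self.G <= 1.0:
            raise ValueError(f"G must lie in [0, 1], got {self.G}")

    @property
    def drive(self) -> float:
        """Compound drive G*I entering the voltage equation."""
        return self.G * self.I


@dataclass
class SRKParams:
    """Sherman–Rinzel–Keizer beta-cell parameters.

    Conductances in pS, voltages in mV, capacitance in fF, calcium in
    uM, time in ms.  Defaults are the classic channel-sharing beta-cell
    parameter set together with the glucose-dependent leak; with G = 0
    they place the single-cell Hopf bifurcation at g_L = 45.21 pS.
    ``Sh`` is negative: h is an inactivation gate, so its logistic runs
    downhill in V.
    """

    Cm: float = 5310.0          # fF
    gK: float = 2500.0          # pS
    gCa: float = 1400.0         # pS
    gKCa: float = 30000.0       # pS
    gL: float = 100.0           # pS (population-2 default excitability)
    VK: float = -75.0           # mV
    VCa: float = 110.0          # mV
    Kd: float = 100.0           # uM
    f: float = 0.001
    alpha: float = 4.5061e-6    # uM fA^-1 ms^-1
    kCa: float = 0.03           # ms^-1
    Vm: float = 4.0             # mV
    Sm: float = 14.0            # mV
    Vn: float = -15.0           # mV
    Sn: float = 5.6             # mV
    Vh: float = -10.0           # mV
    Sh: float = -10.0           # mV  (negative: inactivation)
    tau_bar: float = 60.0       # ms
    V_bar: float = -75.0        # mV
    kappa1: float = 65.0        # mV
    kappa2: float = 20.0        # mV
    G: float = 0.0

    def __post_init__(self) -> None:
        # comparisons via np.any so per-node parameter arrays are accepted
        for name in ("gK", "gCa", "gKCa", "gL"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be non-negative")
        if self.Cm <= 0:
            raise ValueError("Cm must be positive")
        if self.Kd <= 0:
            raise ValueError("Kd must be positive")
        if not 0.0 < self.f <= 1.0:
            raise ValueError("f must lie in (0, 1]")
        G = np.asarray(self.G)
        if np.any(G < 0) or np.any(G > 1):
            raise ValueError(f"G must lie in [0, 1], got {self.G}")


@dataclass
class HopfPoint:
    """Location of a Hopf bifurcation along a one-parameter family."""

    parameter_name: str
    critical_value: float
    eigenvalue_imag: float
    equilibrium: Optional[np.ndarray] = None


class NoHopfInRange(Exception):
    """Raised when no Hopf bifurcation exists in the searched range.

    Raised only by the eigenvalue-bracketing detectors when the bracket
    does not straddle a crossing; the closed-form FHN detector returns
    ``None`` instead of raising (the no-bifurcation case there is a
    well-defined answer, not a search failure).
    """


# --------------------------------------------------------------------------
# FitzHugh–Nagumo
# --------------------------------------------------------------------------

def fhn_rhs(state, params: FHNParams, i_coup: float = 0.0):
    """Time derivative (dV/dt, dW/dt) of a single FHN cell.

    ``i_coup`` is the diffusive coupling current entering the voltage
    equation with a minus sign.  Accepts scalars or arrays (vectorised
    over nodes).
    """
    V, W = state
    if not (np.all(np.isfinite(V)) and np.all(np.isfinite(W))):
        raise FloatingPointError("non-finite FHN state: numerical blow-up")
    dV = V - V**3 / 3.0 - W + params.drive - i_coup
    dW = (V + params.a - params.b * W) / params.tau
    return dV, dW


def fhn_jacobian(V, params: FHNParams):
    """Jacobian of the uncoupled FHN cell at voltage(s) V.

    Returns the 2x2 matrix for scalar V, or the four partials as arrays
    for vector V (used by the network Jacobian assembler).
    """
    dVdV = 1.0 - np.asarray(V) ** 2
    dVdW = -1.0
    dWdV = 1.0 / params.tau
    dWdW = -params.b / params.tau
    if np.isscalar(V) or np.ndim(V) == 0:
        return np.array([[float(dVdV), dVdW], [dWdV, dWdW]])
    return dVdV, dVdW, dWdV, dWdW


def fhn_equilibrium(params: FHNParams, drive: Optional[float] = None) -> float:
    """Equilibrium voltage V* of the uncoupled FHN cell.

    The nullcline intersection satisfies the cubic
    V - V^3/3 - (V + a)/b + drive = 0; the FHN parameter regime used
    here has a unique real root, which is returned.
    """
    d = params.drive if drive is None else drive
    # cubic: -V^3/3 + (1 - 1/b) V - a/b + d = 0
    coeffs = [-1.0 / 3.0, 0.0, 1.0 - 1.0 / params.b, d - params.a / params.b]
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9].real
    if len(real) == 0:  # pragma: no cover - cubic always has a real root
        raise RuntimeError("no real equilibrium found")
    if len(real) > 1:
        # multiple equilibria: return the one on the low-V rest branch
        return float(np.min(real))
    return float(real[0])


def find_hopf_fhn(params: FHNParams) -> Optional[HopfPoint]:
    """Hopf bifurcation of the single FHN cell over the compound drive G*I.

    At an equilibrium V*, the Jacobian trace is 1 - V*^2 - b/tau and the
    determinant is (b (V*^2 - 1) + 1)/tau.  The trace vanishes at
    V* = ±sqrt(1 - b/tau); back-substituting into the equilibrium
    condition gives the critical drive in closed form.  The onset point
    (rest state destabilising as drive increases, the smaller critical
    drive) is returned.  Returns ``None`` when b/tau >= 1 (the trace
    cannot vanish, so no Hopf bifurcation exists).
    """
    b, tau, a = params.b, params.tau, params.a
    if b / tau >= 1.0:
        return None
    vstar = -math.sqrt(1.0 - b / tau)  # onset branch (low-V rest state)
    det = (b * (vstar**2 - 1.0) + 1.0) / tau
    if det <= 0:
        return None
    drive = -vstar + vstar**3 / 3.0 + (vstar + a) / b
    omega = math.sqrt(det)  # at zero trace, eigenvalues are ±i sqrt(det)
    return HopfPoint(
        parameter_name="GI",
        critical_value=drive,
        eigenvalue_imag=omega,
        equilibrium=np.array([vstar, (vstar + a) / b]),
    )


def find_hopf_fhn_eigen(
    params: FHNParams,
    bracket: tuple[float, float] = (0.0, 1.0),
    xtol: float = 1e-10,
) -> HopfPoint:
    """Eigenvalue-based FHN Hopf detection (independent of the closed form).

    Bisects the real part of the leading eigenvalue of the equilibrium
    Jacobian over the compound drive.  Serves as a cross-check oracle
    for :func:`find_hopf_fhn`.
    """

    def re_leading(drive: float) -> float:
        vstar = fhn_equilibrium(params, drive=drive)
        ev = np.linalg.eigvals(fhn_jacobian(vstar, params))
        return float(ev.real.max())

    lo, hi = bracket
    if re_leading(lo) * re_leading(hi) > 0:
        raise NoHopfInRange(f"no real-part sign change in {bracket}")
    crit = brentq(re_leading, lo, hi, xtol=xtol)
    vstar = fhn_equilibrium(params, drive=crit)
    ev = np.linalg.eigvals(fhn_jacobian(vstar, params))
    return HopfPoint(
        parameter_name="GI",
        critical_value=float(crit),
        eigenvalue_imag=float(np.abs(ev.imag).max()),
        equilibrium=np.array([vstar, (vstar + params.a) / params.b]),
    )


# --------------------------------------------------------------------------
# Sherman–Rinzel–Keizer
# --------------------------------------------------------------------------

def srk_gating_steady(V, params: SRKParams, which: Literal["m", "n", "h"]):
    """Steady-state open fraction x_inf(V) = 1 / (1 + exp((V_x - V)/S_x)).

    ``S_h`` is negative in the default table, which turns the logistic
    into a decreasing function of V, realising Ca2+-channel
    inactivation.  Saturates cleanly at 0/1 for extreme voltages.
    """
    if which not in ("m", "n", "h"):
        raise ValueError(f"which must be one of m, n, h; got {which!r}")
    Vx = getattr(params, "V" + which)
    Sx = getattr(params, "S" + which)
    arg = np.clip((Vx - np.asarray(V, dtype=float)) / Sx, -500.0, 500.0)
    out = 1.0 / (1.0 + np.exp(arg))
    return float(out) if np.ndim(V) == 0 else out


def _gating_steady_deriv(V, params: SRKParams, which: str):
    """d x_inf / dV."""
    x = srk_gating_steady(V, params, which)
    Sx = getattr(params, "S" + which)
    return x * (1.0 - x) / Sx


def srk_tau_n(V, params: SRKParams):
    """Voltage-dependent time constant of the K+ activation gate (ms).

    tau_n(V) = tau_bar / (exp((V - V_bar)/kappa1) + exp(-(V - V_bar)/kappa2)).
    Strictly positive; exponent arguments are clipped to avoid overflow
    at unphysical voltages.
    """
    u = np.asarray(V, dtype=float) - params.V_bar
    e1 = np.exp(np.clip(u / params.kappa1, -500.0, 500.0))
    e2 = np.exp(np.clip(-u / params.kappa2, -500.0, 500.0))
    out = params.tau_bar / (e1 + e2)
    return float(out) if np.ndim(V) == 0 else out


def srk_currents(state, params: SRKParams):
    """Ionic currents (I_K, I_Ca, I_KCa, I_L) at the given state.

    Currents are in fA for the default units (pS * mV).  The leak
    carries the glucose drive: I_L = g_L (1 - G) (V - V_K), so I_L
    vanishes identically at G = 1.
    """
    V, n, c = state
    if np.any(np.asarray(c) < 0):
        raise ValueError("calcium concentration must be non-negative")
    minf = srk_gating_steady(V, params, "m")
    hinf = srk_gating_steady(V, params, "h")
    I_K = params.gK * n * (V - params.VK)
    I_Ca = params.gCa * minf * hinf * (V - params.VCa)
    I_KCa = params.gKCa * (c / (params.Kd + c)) * (V - params.VK)
    I_L = params.gL * (1.0 - params.G) * (V - params.VK)
    return I_K, I_Ca, I_KCa, I_L


def srk_rhs(state, params: SRKParams, i_coup: float = 0.0):
    """Time derivative (dV/dt, dn/dt, dc/dt) of a single SRK cell.

    The coupling current enters only the voltage equation, scaled by
    1/Cm.  Vectorised over nodes when the state components are arrays.
    """
    V, n, c = state
    if not (np.all(np.isfinite(V)) and np.all(np.isfinite(n)) and np.all(np.isfinite(c))):
        raise FloatingPointError("non-finite SRK state: numerical blow-up")
    I_K, I_Ca, I_KCa, I_L = srk_currents(state, params)
    dV = (-I_K - I_Ca - I_KCa - I_L - i_coup) / params.Cm
    dn = (srk_gating_steady(V, params, "n") - n) / srk_tau_n(V, params)
    dc = -params.f * (params.alpha * I_Ca + params.kCa * c)
    return dV, dn, dc


def srk_jacobian(state, params: SRKParams):
    """Analytic Jacobian partials of the uncoupled SRK cell.

    For scalar state returns the 3x3 matrix; for per-node arrays returns
    the nine partials (dV/dV, dV/dn, dV/dc, dn/dV, dn/dn, dc/dV, dc/dc;
    dn/dc and dc/dn are zero) as arrays for sparse network assembly.
    """
    V, n, c = state
    p = params
    minf = srk_gating_steady(V, p, "m")
    hinf = srk_gating_steady(V, p, "h")
    dminf = _gating_steady_deriv(V, p, "m")
    dhinf = _gating_steady_deriv(V, p, "h")
    hill = c / (p.Kd + c)
    dhill = p.Kd / (p.Kd + c) ** 2

    dIK_dV = p.gK * n
    dICa_dV = p.gCa * ((dminf * hinf + minf * dhinf) * (V - p.VCa) + minf * hinf)
    dIKCa_dV = p.gKCa * hill
    dIL_dV = p.gL * (1.0 - p.G)
    dVdV = -(dIK_dV + dICa_dV + dIKCa_dV + dIL_dV) / p.Cm
    dVdn = -(p.gK * (V - p.VK)) / p.Cm
    dVdc = -(p.gKCa * dhill * (V - p.VK)) / p.Cm

    ninf = srk_gating_steady(V, p, "n")
    dninf = _gating_steady_deriv(V, p, "n")
    taun = srk_tau_n(V, p)
    # d/dV [ (ninf - n)/taun ] = dninf/taun - (ninf - n) * taun'/taun^2
    u = np.asarray(V, dtype=float) - p.V_bar
    e1 = np.exp(np.clip(u / p.kappa1, -500.0, 500.0))
    e2 = np.exp(np.clip(-u / p.kappa2, -500.0, 500.0))
    dtaun = -p.tau_bar * (e1 / p.kappa1 - e2 / p.kappa2) / (e1 + e2) ** 2
    dndV = dninf / taun - (ninf - n) * dtaun / taun**2
    dndn = -1.0 / taun

    dcdV = -p.f * p.alpha * dICa_dV
    dcdc = -p.f * p.kCa

    if np.ndim(V) == 0:
        return np.array(
            [
                [float(dVdV), float(dVdn), float(dVdc)],
                [float(dndV), float(dndn), 0.0],
                [float(dcdV), 0.0, float(dcdc)],
            ]
        )
    return dVdV, dVdn, dVdc, dndV, dndn, dcdV, dcdc


def srk_equilibrium(
    params: SRKParams,
    v_range: tuple[float, float] = (-74.9, -20.0),
    n_scan: int = 400,
) -> np.ndarray:
    """Rest-state equilibrium (V*, n*, c*) of the uncoupled SRK cell.

    dn/dt = 0 and dc/dt = 0 give n and c explicitly in terms of V, which
    reduces dV/dt = 0 to a scalar root-find.  The voltage axis is
    scanned from the hyperpolarised end and the lowest-V root (the rest
    branch) is bracketed and polished with Brent's method.
    """

    def residual(V: float) -> float:
        n = srk_gating_steady(V, params, "n")
        minf = srk_gating_steady(V, params, "m")
        hinf = srk_gating_steady(V, params, "h")
        I_Ca = params.gCa * minf * hinf * (V - params.VCa)
        c = -params.alpha * I_Ca / params.kCa  # > 0: I_Ca is inward
        I_K = params.gK * n * (V - params.VK)
        I_KCa = params.gKCa * (c / (params.Kd + c)) * (V - params.VK)
        I_L = params.gL * (1.0 - params.G) * (V - params.VK)
        return -(I_K + I_Ca + I_KCa + I_L)

    grid = np.linspace(v_range[0], v_range[1], n_scan)
    vals = np.array([residual(v) for v in grid])
    sign = np.sign(vals)
    crossings = np.where(sign[:-1] * sign[1:] < 0)[0]
    if len(crossings) == 0:
        raise RuntimeError(
            f"no SRK equilibrium found in V range {v_range} "
            f"(gL={params.gL}, G={params.G})"
        )
    i = crossings[0]  # lowest-V root: rest branch
    vstar = brentq(residual, grid[i], grid[i + 1], xtol=1e-12)
    nstar = srk_gating_steady(vstar, params, "n")
    minf = srk_gating_steady(vstar, params, "m")
    hinf = srk_gating_steady(vstar, params, "h")
    I_Ca = params.gCa * minf * hinf * (vstar - params.VCa)
    cstar = -params.alpha * I_Ca / params.kCa
    return np.array([vstar, nstar, cstar])


def _srk_leading_real(params: SRKParams, gL: float) -> tuple[float, float]:
    """Real and |imag| parts of the leading eigenvalue pair at equilibrium.

    Prefers the complex-conjugate pair when one exists (the pair whose
    axis crossing is the Hopf bifurcation); falls back to the largest
    real eigenvalue so that bisection still has a well-defined sign in
    windows where the pair has collided onto the real axis.
    """
    from dataclasses import replace

    p = replace(params, gL=gL)
    eq = srk_equilibrium(p)
    ev = np.linalg.eigvals(srk_jacobian(eq, p))
    cplx = ev[np.abs(ev.imag) > 1e-12]
    if len(cplx) > 0:
        k = int(np.argmax(cplx.real))
        return float(cplx[k].real), float(abs(cplx[k].imag))
    k = int(np.argmax(ev.real))
    return float(ev[k].real), 0.0


def find_hopf_srk(
    params: SRKParams,
    bracket: tuple[float, float] = (5.0, 400.0),
    xtol: float = 1e-6,
) -> HopfPoint:
    """Hopf bifurcation of the single SRK cell over the leak conductance g_L.

    With G fixed (taken from ``params``), bisects the real part of the
    leading eigenvalue pair of the 3x3 equilibrium Jacobian over g_L.
    The returned critical value satisfies the level-set relation
    (1 - G) * g_L(Hopf) = g_L(Hopf at G=0) exactly, because the system
    depends on (g_L, G) only through the product g_L (1 - G).
    """
    lo, hi = bracket
    f_lo, _ = _srk_leading_real(params, lo)
    f_hi, _ = _srk_leading_real(params, hi)
    if f_lo * f_hi > 0:
        raise NoHopfInRange(
            f"real part of leading eigenvalue does not change sign over "
            f"gL in {bracket} at G={params.G} (f({lo})={f_lo:.3g}, "
            f"f({hi})={f_hi:.3g})"
        )
    crit = brentq(lambda g: _srk_leading_real(params, g)[0], lo, hi, xtol=xtol)
    _, omega = _srk_leading_real(params, crit)
    from dataclasses import replace

    eq = srk_equilibrium(replace(params, gL=crit))
    return HopfPoint(
        parameter_name="gL",
        critical_value=float(crit),
        eigenvalue_imag=omega,
        equilibrium=eq,
    )


# --------------------------------------------------------------------------
# Single-cell simulation
# --------------------------------------------------------------------------

#: Default horizons chosen to contain >= 5 oscillations in active regimes.
DEFAULT_T_SPAN = {"fhn": (0.0, 500.0), "srk": (0.0, 300_000.0)}
DEFAULT_N_OUT = {"fhn": 2000, "srk": 20000}


def simulate_single_cell(
    model: Literal["fhn", "srk"],
    params,
    t_span: Optional[tuple[float, float]] = None,
    y0=None,
    n_out: Optional[int] = None,
    rtol: float = 1e-5,
    atol: float = 1e-8,
):
    """Integrate one uncoupled cell with a stiff implicit solver.

    Returns ``(t, y)`` with ``y`` of shape (nvar, n_out).  The solver is
    BDF at relative tolerance 1e-5 with the analytic Jacobian supplied.
    Default initial conditions are the means of the network
    initial-condition distributions (V=-1, W=0 for FHN; V=-68, n=0,
    c=0.57 for SRK).
    """
    if model not in ("fhn", "srk"):
        raise ValueError(f"unknown model {model!r}")
    t_span = DEFAULT_T_SPAN[model] if t_span is None else t_span
    n_out = DEFAULT_N_OUT[model] if n_out is None else n_out
    if model == "fhn":
        if y0 is None:
            y0 = np.array([-1.0, 0.0])
        fun = lambda t, y: np.array(fhn_rhs((y[0], y[1]), params))
        jac = lambda t, y: fhn_jacobian(y[0], params)
    else:
        if y0 is None:
            y0 = np.array([-68.0, 0.0, 0.57])
        fun = lambda t, y: np.array(srk_rhs((y[0], y[1], y[2]), params))
        jac = lambda t, y: srk_jacobian((y[0], y[1], y[2]), params)

    t_eval = np.linspace(t_span[0], t_span[1], n_out)
    sol = solve_ivp(
        fun, t_span, np.asarray(y0, dtype=float),
        method="BDF", jac=jac, rtol=rtol, atol=atol, t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(
            f"single-cell integration failed ({model}, params={asdict(params)}): "
            f"{sol.message}"
        )
    return sol.t, sol.y
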