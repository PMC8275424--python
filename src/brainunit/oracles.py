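"""Independent reference implementations for verifying the solvers.

Nothing here shares discretization code with the production solvers: the
inlet profile is re-evaluated in 50-digit decimal arithmetic, the
semi-discrete ECF system is re-assembled from face fluxes with array
slicing and integrated by an adaptive explicit method, and the passive
steady state is checked against its closed form.  The test suite and the
``verify`` CLI subcommand drive these checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, getcontext

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .ecf import ECFGrid, ECFSolver, ECFState, binding_equilibrium
from .parameters import (
    BindingParams,
    BrainUnitGeometry,
    DrugDoseParams,
    TransportParams,
)
from .plasma import bateman_inlet, bateman_peak_time

__all__ = [
    "OracleReport",
    "bateman_closed_form_check",
    "reference_rhs",
    "ode_reference_check",
    "equilibrium_uniform_check",
]


@dataclass(frozen=True)
class OracleReport:
    """Outcome of one verification case."""

    case: str
    max_abs_deviation: float
    max_rel_deviation: float
    tolerance: float
    passed: bool
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# closed-form inlet profile

def _bateman_decimal(t: float, d: DrugDoseParams) -> Decimal:
    getcontext().prec = 50
    F, Dose, V_d = Decimal(d.F), Decimal(d.Dose), Decimal(d.V_d)
    Ka, Ke, td = Decimal(d.K_a), Decimal(d.K_e), Decimal(t)
    pref = F * Dose * Ka / (V_d * (Ka - Ke))
    return pref * ((-Ke * td).exp() - (-Ka * td).exp())


def bateman_closed_form_check(dosing: DrugDoseParams,
                              t_max: float = 1e5,
                              n_points: int = 200,
                              tolerance: float = 1e-6) -> OracleReport:
    """Check the inlet profile against 50-digit decimal re-evaluation and
    the numerically located concentration peak.

    The value comparison is expected to agree to ~1e-10 relative (pure
    rounding); the peak-location comparison against golden-section
    maximization to within ``tolerance``.
    """
    ts = np.linspace(0.0, t_max, n_points)
    impl = bateman_inlet(ts, dosing)
    ref = np.array([float(_bateman_decimal(t, dosing)) for t in ts])
    scale = float(np.max(np.abs(ref)))
    value_abs = float(np.max(np.abs(impl - ref)))
    value_rel = value_abs / scale if scale > 0 else 0.0

    res = minimize_scalar(lambda t: -bateman_inlet(t, dosing),
                          bounds=(0.0, t_max), method="bounded",
                          options={"xatol": 1e-8 * t_max})
    t_peak_num = float(res.x)
    t_peak = bateman_peak_time(dosing)
    peak_rel = abs(t_peak_num - t_peak) / t_peak

    dev = max(value_rel, peak_rel)
    return OracleReport(
        case="bateman_closed_form",
        max_abs_deviation=value_abs,
        max_rel_deviation=dev,
        tolerance=tolerance,
        passed=bool(dev <= tolerance),
        details={"value_rel": value_rel, "peak_rel": peak_rel,
                 "t_peak_closed_form_s": t_peak, "t_peak_numeric_s": t_peak_num},
    )


# ---------------------------------------------------------------------------
# semi-discrete ECF reference

def reference_rhs(rho: np.ndarray, B1: np.ndarray, B2: np.ndarray,
                  grid: ECFGrid, transport: TransportParams,
                  binding: BindingParams,
                  source_west: np.ndarray | float = 0.0,
                  source_east: np.ndarray | float = 0.0):
    """Time derivatives of the semi-discrete ECF system, assembled from
    face fluxes with array slicing (independent of the sparse-matrix path).

    Fields are (n_x, n_y, n_z) in internal units; returns (dρ, dB1, dB2).
    """
    D = transport.D_star
    v = transport.v_ECF
    drho = np.zeros_like(rho)

    for axis, h in ((0, grid.h_x), (1, grid.h_y), (2, grid.h_z)):
        # diffusive face fluxes; outer faces carry none (sealed / handled
        # by the explicit barrier source)
        diff = np.diff(rho, axis=axis) / h          # gradient on interior faces
        flux = D * diff                              # per-area, toward +axis
        pad = [(0, 0)] * 3
        pad[axis] = (1, 1)
        flux = np.pad(flux, pad)                     # zero at outer faces
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        drho += (flux[tuple(hi)] - flux[tuple(lo)]) / h

    if v > 0:
        for axis, h in ((0, grid.h_x), (2, grid.h_z)):
            take = [slice(None)] * 3
            take[axis] = slice(None, -1)
            adv = v * rho[tuple(take)]               # upwind face flux
            pad = [(0, 0)] * 3
            pad[axis] = (1, 1)
            adv = np.pad(adv, pad)                   # sealed outer faces
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = slice(None, -1)
            hi[axis] = slice(1, None)
            drho -= (adv[tuple(hi)] - adv[tuple(lo)]) / h

    drho[0, :, :] += np.asarray(source_west, float).reshape(rho.shape[1:]) \
        if np.ndim(source_west) else source_west
    drho[-1, :, :] += np.asarray(source_east, float).reshape(rho.shape[1:]) \
        if np.ndim(source_east) else source_east

    dB1 = binding.k1_on_internal * rho * (binding.B1_tot_internal - B1) \
        - binding.k1_off * B1
    dB2 = binding.k2_on_internal * rho * (binding.B2_tot_internal - B2) \
        - binding.k2_off * B2
    return drho - dB1 - dB2, dB1, dB2


def _run_implicit(grid: ECFGrid, transport: TransportParams,
                  binding: BindingParams, dt: float, t_end: float,
                  init: ECFState, source_west, source_east) -> ECFState:
    solver = ECFSolver(grid, transport, binding, dt)
    state = ECFState(init.rho.copy(), init.B1.copy(), init.B2.copy(), init.t)
    for _ in range(int(round(t_end / dt))):
        state = solver.step(state, source_west=source_west, source_east=source_east)
    return state


def ode_reference_check(grid: ECFGrid, transport: TransportParams,
                        binding: BindingParams, *,
                        coarse_dt: float, t_end: float,
                        init: ECFState | None = None,
                        source_west: np.ndarray | float = 0.0,
                        source_east: np.ndarray | float = 0.0,
                        ratio_window: tuple[float, float] = (1.6, 2.4),
                        deviation_tolerance: float | None = None) -> OracleReport:
    """Compare the implicit solver against a high-accuracy explicit
    integration of the identical semi-discrete system.

    Runs the implicit solver at ``coarse_dt`` and ``coarse_dt/2`` and
    asserts first-order convergence: the deviation from the reference
    roughly halves (Richardson ratio inside ``ratio_window``).  If
    ``deviation_tolerance`` is given, the coarse deviation itself must
    also stay below it (relative to the field scale).
    """
    if init is None:
        init = ECFState.zeros(grid)
    shape = grid.shape
    n = grid.n_cells

    def rhs_flat(t, y):
        rho = y[:n].reshape(shape)
        B1 = y[n:2 * n].reshape(shape)
        B2 = y[2 * n:].reshape(shape)
        drho, dB1, dB2 = reference_rhs(rho, B1, B2, grid, transport, binding,
                                       source_west, source_east)
        return np.concatenate([drho.ravel(), dB1.ravel(), dB2.ravel()])

    y0 = np.concatenate([init.rho.ravel(), init.B1.ravel(), init.B2.ravel()])
    scale = max(float(np.max(np.abs(y0))), 1e-30)
    sol = solve_ivp(rhs_flat, (0.0, t_end), y0, method="DOP853",
                    rtol=1e-11, atol=1e-14 * scale, dense_output=False,
                    t_eval=[t_end])
    if not sol.success:
        raise RuntimeError(f"reference integration failed: {sol.message}")
    ref = sol.y[:, -1]

    devs = []
    for dt in (coarse_dt, coarse_dt / 2):
        s = _run_implicit(grid, transport, binding, dt, t_end, init,
                          source_west, source_east)
        y = np.concatenate([s.rho.ravel(), s.B1.ravel(), s.B2.ravel()])
        devs.append(float(np.max(np.abs(y - ref))))
    ref_scale = max(float(np.max(np.abs(ref))), 1e-30)
    ratio = devs[0] / devs[1] if devs[1] > 0 else np.inf
    rel_dev = devs[0] / ref_scale
    ok = ratio_window[0] <= ratio <= ratio_window[1]
    if deviation_tolerance is not None:
        ok = ok and rel_dev <= deviation_tolerance
    return OracleReport(
        case="ode_reference",
        max_abs_deviation=devs[0],
        max_rel_deviation=rel_dev,
        tolerance=deviation_tolerance if deviation_tolerance is not None else np.inf,
        passed=bool(ok),
        details={"richardson_ratio": ratio, "dev_coarse": devs[0],
                 "dev_half": devs[1], "ratio_window": list(ratio_window)},
    )


# ---------------------------------------------------------------------------
# passive uniform steady state

def equilibrium_uniform_check(c_umol_per_L: float = 1.0, *,
                              geometry: BrainUnitGeometry | None = None,
                              binding: BindingParams | None = None,
                              P: float = 1e-6, D_star: float = 5e-12,
                              n: int = 5, dt: float = 5.0, t_end: float = 8000.0,
                              tolerance: float = 1e-4) -> OracleReport:
    """Verify convergence of the ECF field to the passive steady state.

    With the plasma clamped uniform at concentration ``c``, no active
    transport and no bulk flow, the free ECF field must converge to ``c``
    and each bound pool to its closed-form equilibrium, with the
    volume-integrated free drug increasing monotonically.  The transport
    parameters default to values that equilibrate on a convenient
    timescale (the property is parameter-independent).
    """
    from .parameters import default_parameters

    defaults = default_parameters()
    geometry = geometry or defaults.geometry
    binding = binding or defaults.binding
    transport = TransportParams(D_star=D_star, v_ECF=0.0, v_blood=0.0)
    grid = ECFGrid.from_geometry(geometry, n, n, n)
    solver = ECFSolver(grid, transport, binding, dt)
    c = c_umol_per_L * 1e3                      # internal μmol·m⁻³
    state = ECFState.zeros(grid)
    totals = [0.0]
    face_over_volume = 1.0 / grid.h_x
    monotone = True
    for _ in range(int(round(t_end / dt))):
        src_w = P * (c - state.rho[0, :, :].ravel()) * face_over_volume
        src_e = P * (c - state.rho[-1, :, :].ravel()) * face_over_volume
        state = solver.step(state, source_west=src_w, source_east=src_e)
        total = float(state.rho.sum())
        if total < totals[-1] * (1 - 1e-12) - 1e-30:
            monotone = False
        totals.append(total)

    rho_dev = float(np.max(np.abs(state.rho - c))) / (c if c > 0 else 1.0)
    b_devs = []
    for B, k_on, k_off, B_tot in ((state.B1, binding.k1_on_internal,
                                   binding.k1_off, binding.B1_tot_internal),
                                  (state.B2, binding.k2_on_internal,
                                   binding.k2_off, binding.B2_tot_internal)):
        if k_on == 0 and k_off == 0:
            continue
        eq = binding_equilibrium(c, k_on, k_off, B_tot)
        ref = eq if eq > 0 else 1.0
        b_devs.append(float(np.max(np.abs(B - eq))) / ref)
    dev = max([rho_dev] + b_devs)
    return OracleReport(
        case="equilibrium_uniform",
        max_abs_deviation=dev * c,
        max_rel_deviation=dev,
        tolerance=tolerance,
        passed=bool(dev <= tolerance and monotone),
        details={"rho_rel_dev": rho_dev, "bound_rel_devs": b_devs,
                 "monotone": monotone},
    )
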