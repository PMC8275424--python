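"""Brain-ECF reaction-advection-diffusion with two-class reversible binding.

The free drug ρ in the extracellular fluid obeys

    ∂ρ/∂t = D* ∇²ρ − v_ECF (∂ρ/∂x + ∂ρ/∂z)
            − k1_on ρ (B1_tot − B1) + k1_off B1
            − k2_on ρ (B2_tot − B2) + k2_off B2

with the bound pools B1 (specific targets) and B2 (nonspecific tissue)
following the matching association/dissociation ODEs.  The ECF domain is
the box [r, x_r − r] × [0, y_r] × [0, z_r]; the faces x = r and
x = x_r − r are the blood-brain barrier, where the exchange flux enters
through a ghost-face balance, and every other face is sealed
(zero normal flux, the discrete form of the zero-normal-gradient closure).

Discretization: cell-centered 7-point Laplacian, flux-form first-order
upwind advection along +x and +z with sealed outer faces, backward Euler in
time.  The bilinear binding terms are linearized by lagging ρ in the
denominator of the implicit bound-pool update, which makes B_i^{n+1} an
affine function of ρ^{n+1}; substituting it into the ρ equation keeps the
step a single sparse linear solve and transfers mass between free and
bound pools *exactly* (binding redistributes, never creates, drug).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .parameters import (
    UMOL_PER_L_TO_UMOL_PER_M3,
    BindingParams,
    BrainUnitGeometry,
    TransportParams,
)

__all__ = [
    "binding_rate",
    "binding_equilibrium",
    "ECFGrid",
    "ECFState",
    "ECFSolver",
    "total_masses",
]

# round-off guard for the positivity / box invariant checks: values below
# -guard·scale indicate a genuine solver defect, not accumulation of
# floating-point noise in drug-free regions
_INVARIANT_GUARD = 1e-11


def binding_rate(rho, B, k_on: float, k_off: float, B_tot: float):
    """Net association rate dB/dt = k_on·ρ·(B_tot − B) − k_off·B.

    Unit-agnostic: ρ, B, B_tot must share one concentration basis and k_on
    must be the inverse of (that basis × time).
    """
    rho = np.asarray(rho, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.any(B > B_tot * (1 + 1e-12)) or np.any(B < 0):
        raise ValueError("bound concentration outside [0, B_tot]")
    out = k_on * rho * (B_tot - B) - k_off * B
    return float(out) if out.ndim == 0 else out


def binding_equilibrium(rho, k_on: float, k_off: float, B_tot: float):
    """Fixed point of the binding ODE at constant ρ: B_tot·k_on·ρ/(k_on·ρ + k_off)."""
    rho = np.asarray(rho, dtype=float)
    denom = k_on * rho + k_off
    if np.any(denom <= 0):
        raise ValueError("k_on·ρ + k_off must be positive for a defined equilibrium")
    out = B_tot * k_on * rho / denom
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ECFGrid:
    """Cell-centered grid over the ECF box [r, x_r − r] × [0, y_r] × [0, z_r]."""

    n_x: int
    n_y: int
    n_z: int
    x_min: float
    x_max: float
    y_max: float
    z_max: float

    @classmethod
    def from_geometry(cls, geometry: BrainUnitGeometry,
                      n_x: int, n_y: int, n_z: int) -> "ECFGrid":
        L = geometry.unit_length
        return cls(n_x=n_x, n_y=n_y, n_z=n_z,
                   x_min=geometry.r, x_max=L - geometry.r, y_max=L, z_max=L)

    @property
    def h_x(self) -> float:
        return (self.x_max - self.x_min) / self.n_x

    @property
    def h_y(self) -> float:
        return self.y_max / self.n_y

    @property
    def h_z(self) -> float:
        return self.z_max / self.n_z

    @property
    def cell_volume(self) -> float:
        return self.h_x * self.h_y * self.h_z

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_x, self.n_y, self.n_z)

    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_y * self.n_z

    def axis_centers(self, axis: str) -> np.ndarray:
        """Cell-center coordinates (m) along 'x', 'y' or 'z'."""
        if axis == "x":
            return self.x_min + (np.arange(self.n_x) + 0.5) * self.h_x
        if axis == "y":
            return (np.arange(self.n_y) + 0.5) * self.h_y
        if axis == "z":
            return (np.arange(self.n_z) + 0.5) * self.h_z
        raise ValueError(f"unknown axis '{axis}'")

    def face_centers_yz(self) -> np.ndarray:
        """(n_y·n_z, 2) array of barrier-face centers, C-order over (y, z)."""
        yc = self.axis_centers("y")
        zc = self.axis_centers("z")
        Y, Z = np.meshgrid(yc, zc, indexing="ij")
        return np.column_stack([Y.ravel(), Z.ravel()])


@dataclass
class ECFState:
    """Free and bound concentration fields at one time (internal μmol·m⁻³)."""

    rho: np.ndarray
    B1: np.ndarray
    B2: np.ndarray
    t: float = 0.0

    @classmethod
    def zeros(cls, grid: ECFGrid) -> "ECFState":
        return cls(rho=np.zeros(grid.shape), B1=np.zeros(grid.shape),
                   B2=np.zeros(grid.shape), t=0.0)

    def in_umol_per_L(self, field: str) -> np.ndarray:
        return getattr(self, field) / UMOL_PER_L_TO_UMOL_PER_M3


def total_masses(state: ECFState, grid: ECFGrid) -> tuple[float, float, float]:
    """Volume integrals (μmol) of free, specifically and nonspecifically bound drug."""
    v = grid.cell_volume
    return (float(state.rho.sum() * v),
            float(state.B1.sum() * v),
            float(state.B2.sum() * v))


class ECFSolver:
    """Backward-Euler step of the coupled ρ/B1/B2 system on one grid.

    The constant transport operator (diffusion + advection + sealed
    boundaries) is assembled and LU-factorized once; the per-step binding
    diagonal is folded in by a fixed-point iteration preconditioned with
    that factorization (the binding diagonal is O(dt·k_on·B_tot) ≪ 1, so a
    handful of iterations reach machine accuracy).
    """

    def __init__(self, grid: ECFGrid, transport: TransportParams,
                 binding: BindingParams, dt: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.grid = grid
        self.transport = transport
        self.binding = binding
        self.dt = dt
        self._assemble()

    # -- operator assembly --------------------------------------------------

    def _assemble(self) -> None:
        g = self.grid
        n = g.n_cells
        D = self.transport.D_star
        v = self.transport.v_ECF
        shape = g.shape

        idx = np.arange(n).reshape(shape)
        rows, cols, vals = [], [], []

        def add(r, c, val):
            rows.append(np.ravel(r))
            cols.append(np.ravel(c))
            vals.append(np.broadcast_to(val, np.ravel(r).shape).astype(float))

        # 7-point Laplacian, homogeneous Neumann on every face (the barrier
        # flux enters separately as a per-cell source)
        for axis, h in ((0, g.h_x), (1, g.h_y), (2, g.h_z)):
            c = D / h**2
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = slice(None, -1)
            hi[axis] = slice(1, None)
            a, b = idx[tuple(lo)], idx[tuple(hi)]
            add(a, b, c)
            add(a, a, -c)
            add(b, a, c)
            add(b, b, -c)

        # flux-form upwind advection along +x and +z, sealed outer faces
        if v > 0:
            for axis, h in ((0, g.h_x), (2, g.h_z)):
                c = v / h
                lo = [slice(None)] * 3
                hi = [slice(None)] * 3
                lo[axis] = slice(None, -1)
                hi[axis] = slice(1, None)
                up, down = idx[tuple(lo)], idx[tuple(hi)]
                add(down, up, c)   # gain through upstream face
                add(up, up, -c)    # loss through downstream face
        A = sp.csr_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n, n))
        A.sum_duplicates()
        self._A = A
        self._K = (-self.dt * A).tocsr()   # M = I + K + diag(beta)
        absK = abs(self._K)
        self._K_norm = float(absK.sum(axis=1).max())
        self._lu = None                     # factorized lazily for large dt

        # linear indices of the barrier boundary cells, C-order over (y, z)
        self._west_cells = idx[0, :, :].ravel()
        self._east_cells = idx[-1, :, :].ravel()

    @property
    def transport_matrix(self) -> sp.csr_matrix:
        """Semi-discrete transport operator A (dρ/dt = Aρ + sources)."""
        return self._A

    def _solve(self, rhs: np.ndarray, beta_sum: np.ndarray) -> np.ndarray:
        """Solve (I + K + diag(beta_sum)) x = rhs to machine accuracy.

        For the desk-scale time steps the iteration matrix K + diag(beta)
        has ∞-norm ≪ 1, so plain fixed-point iteration x ← rhs − (K+β)x
        converges geometrically and costs only sparse matvecs.  For large
        dt the system is LU-factorized per step instead (still
        unconditionally stable, just pricier).
        """
        kappa = self._K_norm + float(np.max(beta_sum, initial=0.0))
        if kappa <= 0.5:
            x = rhs.copy()
            scale = max(float(np.max(np.abs(rhs))), 1e-300)
            prev_delta = np.inf
            for _ in range(200):
                x_new = rhs - self._K @ x - beta_sum * x
                delta = float(np.max(np.abs(x_new - x)))
                x = x_new
                # converged, or stalled at the rounding floor
                if delta <= 1e-15 * scale or delta >= prev_delta * 0.9:
                    return x
                prev_delta = delta
            raise FloatingPointError("ECF fixed-point solve did not converge")
        M = (sp.eye(self.grid.n_cells) + self._K
             + sp.diags(np.broadcast_to(beta_sum, (self.grid.n_cells,)))).tocsc()
        x = spla.splu(M).solve(rhs)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("ECF direct solve produced non-finite values")
        return x

    # -- time stepping ------------------------------------------------------

    def step(self, state: ECFState,
             source_west: np.ndarray | float = 0.0,
             source_east: np.ndarray | float = 0.0,
             check_invariants: bool = True) -> ECFState:
        """Advance (ρ, B1, B2) by one implicit step.

        ``source_west``/``source_east`` are volumetric barrier-exchange
        rates (μmol·m⁻³·s⁻¹) for the boundary cells of each barrier plane,
        flattened over (y, z); they are held fixed during the step.
        """
        g = self.grid
        dt = self.dt
        b = self.binding
        rho_n = state.rho.ravel()

        src = np.zeros(g.n_cells)
        np.add.at(src, self._west_cells,
                  np.broadcast_to(np.asarray(source_west, float), self._west_cells.shape))
        np.add.at(src, self._east_cells,
                  np.broadcast_to(np.asarray(source_east, float), self._east_cells.shape))

        # affine implicit bound-pool updates: B^{n+1} = alpha + beta·ρ^{n+1}
        alphas, betas = [], []
        for B_n, k_on, k_off, B_tot in (
            (state.B1.ravel(), b.k1_on_internal, b.k1_off, b.B1_tot_internal),
            (state.B2.ravel(), b.k2_on_internal, b.k2_off, b.B2_tot_internal),
        ):
            denom = 1.0 + dt * (k_on * rho_n + k_off)
            alphas.append(B_n / denom)
            betas.append(dt * k_on * B_tot / denom)

        beta_sum = betas[0] + betas[1]
        rhs = rho_n + dt * src \
            + (state.B1.ravel() - alphas[0]) + (state.B2.ravel() - alphas[1])

        rho_new = self._solve(rhs, beta_sum)

        B1_new = alphas[0] + betas[0] * rho_new
        B2_new = alphas[1] + betas[1] * rho_new

        new = ECFState(rho=rho_new.reshape(g.shape),
                       B1=B1_new.reshape(g.shape),
                       B2=B2_new.reshape(g.shape),
                       t=state.t + dt)
        if check_invariants:
            self._check_invariants(new)
        return new

    def _check_invariants(self, state: ECFState) -> None:
        guard = _INVARIANT_GUARD
        scale = max(float(np.max(np.abs(state.rho))), 1e-300)
        if float(np.min(state.rho)) < -guard * scale:
            raise FloatingPointError(
                f"negative free concentration after step (min {np.min(state.rho):.3e})")
        for B, tot, name in ((state.B1, self.binding.B1_tot_internal, "B1"),
                             (state.B2, self.binding.B2_tot_internal, "B2")):
            lo, hi = float(np.min(B)), float(np.max(B))
            ref = max(tot, 1e-300)
            if lo < -guard * ref or hi > tot + guard * ref:
                raise FloatingPointError(
                    f"{name} outside [0, B_tot] after step (range [{lo:.3e}, {hi:.3e}])")
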