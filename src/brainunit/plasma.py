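"""Capillary network plasma transport.

The brain unit's capillaries are the twelve edges of the cube, grouped as
four x-, four y- and four z-directed vessels.  Blood enters at the arteriole
corner ``W_in = (0, 0, 0)`` and drains at the venule corner
``W_out = (x_r, y_r, z_r)``; every edge is directed along its increasing
coordinate, i.e. away from the inlet.  Plasma diffusion is neglected, so
each capillary is a pure advection channel and the plasma concentration μ
is a 1-D field on the edge graph.

At an interior vertex the outgoing edges receive the arithmetic mean of the
incoming end concentrations (equal vessel sizes and speeds).  Volumetric
flow then splits 3-ways at the inlet and 2-ways at the inlet-adjacent
corners, so the six "middle" edges each carry half the flow of the six
edges touching the inlet or outlet.  Weighting each edge's cross-section by
this flow share makes first-order upwind advection exactly conservative:
the discrete plasma mass changes only through inlet inflow and outlet
outflow (see :meth:`PlasmaSolver.mass`).

Time stepping is backward Euler, which together with upwinding yields an
M-matrix system: unconditionally stable and positivity-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .parameters import (
    UMOL_PER_L_TO_UMOL_PER_M3,
    BrainUnitGeometry,
    DrugDoseParams,
)

__all__ = [
    "bateman_inlet",
    "CapillaryEdge",
    "CapillaryGraph",
    "build_capillary_graph",
    "PlasmaState",
    "PlasmaSolver",
]


def bateman_inlet(t, dosing: DrugDoseParams):
    """Unbound plasma concentration at the inlet after an oral dose (μmol·L⁻¹).

    Two-exponential profile of one-compartment first-order absorption (K_a)
    and elimination (K_e):

        μ_in(t) = F·Dose·K_a / (V_d·(K_a − K_e)) · (e^(−K_e·t) − e^(−K_a·t))

    Accepts scalar or array ``t`` (s); negative times are rejected.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    d = dosing
    pref = d.F * d.Dose * d.K_a / (d.V_d * (d.K_a - d.K_e))
    out = pref * (np.exp(-d.K_e * t) - np.exp(-d.K_a * t))
    return float(out) if out.ndim == 0 else out


def bateman_peak_time(dosing: DrugDoseParams) -> float:
    """Time of the inlet concentration maximum, ln(K_a/K_e)/(K_a − K_e) (s)."""
    return float(np.log(dosing.K_a / dosing.K_e) / (dosing.K_a - dosing.K_e))


@dataclass(frozen=True)
class CapillaryEdge:
    """One directed capillary segment (a cube edge)."""

    axis: int                 # 0=x, 1=y, 2=z
    index: int                # 1..4 within its axis family
    tail: int                 # global node id of upstream vertex
    head: int                 # global node id of downstream vertex
    nodes: np.ndarray         # global node ids, tail..head, length n
    flow_weight: float        # volumetric flow share relative to an inlet edge


@dataclass(frozen=True)
class CapillaryGraph:
    """The 12-edge directed cube graph with per-edge 1-D nodes.

    ``coords[i]`` is the 3-D position (m) of global node ``i``; the eight
    cube corners occupy ids 0..7 (id = 4·bx + 2·by + bz from the corner's
    0/1 coordinates), interior nodes follow edge by edge.
    """

    edges: tuple[CapillaryEdge, ...]
    coords: np.ndarray        # (N, 3) node positions (m)
    h: float                  # node spacing along an edge (m)
    unit_length: float        # cube edge length (m)
    capillary_radius: float   # r (m)
    inlet: int = 0            # W_in node id
    outlet: int = 7           # W_out node id

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    def in_degree(self, v: int) -> int:
        return sum(1 for e in self.edges if e.head == v)

    def out_degree(self, v: int) -> int:
        return sum(1 for e in self.edges if e.tail == v)

    @property
    def node_volumes(self) -> np.ndarray:
        """Flow-weighted plasma volume owned by each node (m³).

        Each edge contributes ``flow_weight · π r² · h`` per interior node
        and half that to each of its end vertices.  With equal speeds on
        all edges this weighting is the unique one under which upwind
        advection conserves the discrete mass ∑ V_i μ_i exactly.
        """
        area = np.pi * self.capillary_radius**2
        vol = np.zeros(self.n_nodes)
        for e in self.edges:
            w = e.flow_weight * area * self.h
            vol[e.nodes[1:-1]] += w
            vol[e.nodes[0]] += 0.5 * w
            vol[e.nodes[-1]] += 0.5 * w
        return vol


def build_capillary_graph(geometry: BrainUnitGeometry, n_nodes_per_edge: int) -> CapillaryGraph:
    """Construct the cube capillary graph with ``n_nodes_per_edge`` nodes per edge.

    Nodes are uniformly spaced (spacing ``unit_length/(n−1)``); the eight
    corner vertices are shared between their three adjacent edges.
    """
    if n_nodes_per_edge < 2:
        raise ValueError("need at least 2 nodes per edge")
    n = n_nodes_per_edge
    L = geometry.unit_length
    h = L / (n - 1)

    corners = np.array([[bx, by, bz] for bx in (0, 1) for by in (0, 1) for bz in (0, 1)],
                       dtype=float) * L
    coords = [corners]
    next_id = 8
    edges = []
    axis_counter = {0: 0, 1: 0, 2: 0}
    for axis in range(3):
        for bits in ((0, 0), (0, 1), (1, 0), (1, 1)):
            tail_bits = [0, 0, 0]
            other_axes = [a for a in range(3) if a != axis]
            tail_bits[other_axes[0]], tail_bits[other_axes[1]] = bits
            head_bits = list(tail_bits)
            head_bits[axis] = 1
            tail = 4 * tail_bits[0] + 2 * tail_bits[1] + tail_bits[2]
            head = 4 * head_bits[0] + 2 * head_bits[1] + head_bits[2]
            interior_ids = np.arange(next_id, next_id + n - 2)
            next_id += n - 2
            node_ids = np.concatenate(([tail], interior_ids, [head])).astype(int)
            pts = np.repeat(corners[tail][None, :], n - 2, axis=0)
            pts[:, axis] = (np.arange(1, n - 1) * h) + corners[tail][axis]
            coords.append(pts)
            # flow share: edges leaving the inlet or entering the outlet carry
            # a full third of the flow; the six middle edges carry half that
            layer = sum(tail_bits)  # 0 = inlet edge, 1 = middle, 2 = outlet edge
            weight = 1.0 if layer in (0, 2) else 0.5
            axis_counter[axis] += 1
            edges.append(CapillaryEdge(axis=axis, index=axis_counter[axis],
                                       tail=tail, head=head,
                                       nodes=node_ids, flow_weight=weight))
    return CapillaryGraph(edges=tuple(edges), coords=np.vstack(coords), h=h,
                          unit_length=L, capillary_radius=geometry.r)


@dataclass
class PlasmaState:
    """Plasma concentration on the capillary graph at one time.

    ``mu`` is in internal units (μmol·m⁻³); initially zero everywhere.
    """

    mu: np.ndarray
    t: float = 0.0

    @property
    def mu_umol_per_L(self) -> np.ndarray:
        return self.mu / UMOL_PER_L_TO_UMOL_PER_M3


class PlasmaSolver:
    """Backward-Euler upwind advection on the capillary graph.

    The inlet vertex is clamped to the prescribed inlet concentration and
    the outlet vertex to zero (instant venule drainage); interior vertices
    mix incoming edges by arithmetic mean.  The system matrix is assembled
    once per (graph, v_blood, dt) and LU-factorized.
    """

    def __init__(self, graph: CapillaryGraph, v_blood: float, dt: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        if v_blood < 0:
            raise ValueError("v_blood must be non-negative")
        self.graph = graph
        self.v_blood = v_blood
        self.dt = dt
        self._assemble()

    def _assemble(self) -> None:
        g = self.graph
        N = g.n_nodes
        c = self.v_blood / g.h
        A = sp.lil_matrix((N, N))
        for e in g.edges:
            ids = e.nodes
            # interior nodes and the head vertex upwind from their predecessor;
            # head vertices with several incoming edges average them below
            for j in range(1, len(ids) - 1):
                A[ids[j], ids[j]] += c
                A[ids[j], ids[j - 1]] -= c
        for v in range(8):
            if v in (g.inlet, g.outlet):
                continue
            incoming = [e for e in g.edges if e.head == v]
            if not incoming:
                continue
            d = len(incoming)
            A[v, v] += c
            for e in incoming:
                A[v, e.nodes[-2]] -= c / d
        self._A = A.tocsr()
        M = (sp.eye(N) + self.dt * self._A).tolil()
        # Dirichlet rows: inlet clamped, outlet drained
        for v in (g.inlet, g.outlet):
            M.rows[v] = [v]
            M.data[v] = [1.0]
        self._M = M.tocsc()
        self._lu = spla.splu(self._M)
        self._volumes = g.node_volumes
        mask = np.ones(N, dtype=bool)
        mask[[g.inlet, g.outlet]] = False
        self._interior_mask = mask
        # nodes straddling the Dirichlet vertices, for the flux bookkeeping
        self._post_inlet = np.array([e.nodes[1] for e in g.edges if e.tail == g.inlet])
        self._pre_outlet = np.array([e.nodes[-2] for e in g.edges if e.head == g.outlet])

    def mass(self, state: PlasmaState) -> float:
        """Discrete plasma drug mass ∑ V_i μ_i over non-Dirichlet nodes (μmol)."""
        return float(np.sum((self._volumes * state.mu)[self._interior_mask]))

    def step(self, state: PlasmaState, inlet_value: float,
             bbb_sink: np.ndarray | float = 0.0) -> tuple[PlasmaState, dict[str, float]]:
        """Advance μ by one implicit step.

        Parameters
        ----------
        inlet_value
            Inlet concentration to clamp at ``W_in`` (internal μmol·m⁻³).
        bbb_sink
            Per-node rate of concentration change due to BBB exchange
            (μmol·m⁻³·s⁻¹, negative = loss to the ECF), applied explicitly.

        Returns the new state and a bookkeeping dict with the inlet inflow
        and outlet outflow of this step (μmol), computed from the upwind
        face fluxes of the assembled operator.
        """
        if inlet_value < 0:
            raise ValueError("inlet concentration must be non-negative")
        g = self.graph
        rhs = state.mu + self.dt * np.broadcast_to(np.asarray(bbb_sink, dtype=float),
                                                   state.mu.shape)
        rhs = rhs.copy()
        rhs[g.inlet] = inlet_value
        rhs[g.outlet] = 0.0
        mu_new = self._lu.solve(rhs)
        if not np.all(np.isfinite(mu_new)):
            raise FloatingPointError("plasma advection solve produced non-finite values")
        area = np.pi * g.capillary_radius**2
        inflow = self.v_blood * area * inlet_value * len(self._post_inlet) * self.dt
        outflow = self.v_blood * area * float(np.sum(mu_new[self._pre_outlet])) * self.dt
        return (PlasmaState(mu=mu_new, t=state.t + self.dt),
                {"inflow": inflow, "outflow": outflow})

    @property
    def advection_matrix(self) -> sp.csr_matrix:
        """The assembled advection operator A (dμ/dt = −Aμ), pre-Dirichlet."""
        return self._A
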