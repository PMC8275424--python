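"""Blood-brain-barrier flux law and plasma↔ECF exchange assembly.

The per-area barrier flux combines passive permeation with saturable
carrier transport (positive = blood → ECF)::

    f(μ, ρ) = P·(μ − ρ)
              + T_m_in  / (SA_BBB · (K_m_in  + μ)) · μ
              − T_m_out / (SA_BBB · (K_m_out + ρ)) · ρ

evaluated in internal units (concentrations μmol·m⁻³), so every term is a
molar flux density in μmol·m⁻²·s⁻¹.  Exchange happens on the two x-normal
barrier planes ``x = r`` and ``x = x_r − r``; each boundary cell of the ECF
grid is paired with its nearest plasma node on the four capillary edges
bounding that face of the cube, and the drug removed from a plasma node
equals the drug added to its paired cells exactly (per-pair conservation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import BBBParams
from .plasma import CapillaryGraph

__all__ = [
    "BBBFluxResult",
    "bbb_flux",
    "compose_permeability",
    "ExchangePlan",
    "assemble_exchange_terms",
    "exchange_rates",
]


@dataclass(frozen=True)
class BBBFluxResult:
    """Decomposed barrier flux density (μmol·m⁻²·s⁻¹, internal units)."""

    total_flux: np.ndarray | float
    passive_part: np.ndarray | float
    active_in_part: np.ndarray | float
    active_out_part: np.ndarray | float


def bbb_flux(mu, rho, params: BBBParams) -> BBBFluxResult:
    """Evaluate the barrier flux law at plasma/ECF concentrations μ, ρ.

    ``mu`` and ``rho`` are internal concentrations (μmol·m⁻³), scalar or
    broadcastable arrays.  Sign convention: positive = blood → ECF.
    """
    mu = np.asarray(mu, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(mu < 0) or np.any(rho < 0):
        raise ValueError("concentrations must be non-negative")
    P = params.permeability
    passive = P * (mu - rho)
    if params.T_m_in > 0 or params.T_m_out > 0:
        sa = params.SA_BBB
        active_in = params.T_m_in / (sa * (params.K_m_in_internal + mu)) * mu
        active_out = params.T_m_out / (sa * (params.K_m_out_internal + rho)) * rho
    else:
        active_in = np.zeros_like(mu)
        active_out = np.zeros_like(rho)
    total = passive + active_in - active_out
    if total.ndim == 0:
        return BBBFluxResult(float(total), float(passive),
                             float(active_in), float(active_out))
    return BBBFluxResult(total, passive, active_in, active_out)


def compose_permeability(p_trans: float, f_trans: float, D_para: float,
                         W_PCS: float, f_para: float) -> float:
    """Compose P from transcellular and paracellular routes (m·s⁻¹).

    P = p_trans·f_trans + p_para·f_para with p_para = D_para/W_PCS.
    Warns if the two surface fractions together exceed one.
    """
    if not (0.0 <= f_trans <= 1.0 and 0.0 <= f_para <= 1.0):
        raise ValueError("surface fractions must lie in [0, 1]")
    if W_PCS <= 0:
        raise ValueError("paracellular-space width must be positive")
    if f_trans + f_para > 1.0:
        import warnings

        warnings.warn("f_trans + f_para exceed 1: fractions of the same surface",
                      stacklevel=2)
    return p_trans * f_trans + (D_para / W_PCS) * f_para


@dataclass(frozen=True)
class ExchangePlan:
    """Precomputed pairing of ECF barrier cells with plasma nodes.

    For each of the two barrier planes (0 = west, ``x = r``; 1 = east,
    ``x = x_r − r``) the plan stores, per boundary cell (flattened over the
    (y, z) face): the paired plasma node id, the exchange face area (m²),
    and the receiving ECF cell's linear index on that face.
    """

    plane_nodes: tuple[np.ndarray, np.ndarray]    # paired plasma node per cell
    face_area: float                              # h_y·h_z per cell face (m²)
    plasma_volumes: np.ndarray                    # node volume V_i (m³)
    plane_node_sets: tuple[np.ndarray, np.ndarray]  # unique node ids per plane


def assemble_exchange_terms(graph: CapillaryGraph, face_centers_yz: np.ndarray,
                            face_area: float) -> ExchangePlan:
    """Pair each ECF barrier cell with its nearest plasma node.

    ``face_centers_yz`` is an (n_cells, 2) array of the (y, z) centers of
    the boundary-cell faces (identical for both planes by symmetry of the
    grid).  The candidate plasma nodes for the west plane are those on the
    four cube edges lying in the plane ``x = 0``, and for the east plane
    those in ``x = L``; pairing minimizes the (y, z) distance.
    """
    if face_centers_yz.ndim != 2 or face_centers_yz.shape[1] != 2:
        raise ValueError("face_centers_yz must be (n, 2)")
    L = graph.unit_length
    plane_nodes = []
    plane_sets = []
    for x_plane in (0.0, L):
        on_plane = np.flatnonzero(np.abs(graph.coords[:, 0] - x_plane) < 1e-12 * L)
        # the arteriole and venule corners are Dirichlet reservoirs, not
        # exchanging capillary wall
        on_plane = on_plane[(on_plane != graph.inlet) & (on_plane != graph.outlet)]
        if on_plane.size == 0:
            raise ValueError("no plasma nodes found on a barrier plane")
        cand_yz = graph.coords[on_plane][:, 1:]
        d2 = ((face_centers_yz[:, None, :] - cand_yz[None, :, :]) ** 2).sum(axis=2)
        nearest = on_plane[np.argmin(d2, axis=1)]
        plane_nodes.append(nearest)
        plane_sets.append(np.unique(nearest))
    return ExchangePlan(plane_nodes=(plane_nodes[0], plane_nodes[1]),
                        face_area=face_area,
                        plasma_volumes=graph.node_volumes,
                        plane_node_sets=(plane_sets[0], plane_sets[1]))


def exchange_rates(plan: ExchangePlan, params: BBBParams,
                   mu: np.ndarray, rho_west: np.ndarray, rho_east: np.ndarray,
                   ecf_cell_volume: float,
                   coupling: str = "plane_mean") -> tuple[np.ndarray, np.ndarray,
                                                          np.ndarray, float]:
    """Turn the flux law into paired volumetric source/sink rates.

    Parameters
    ----------
    mu
        Plasma concentration on all graph nodes (μmol·m⁻³).
    rho_west, rho_east
        ECF free concentration in the boundary cells of each barrier plane,
        flattened over the (y, z) face (μmol·m⁻³).
    ecf_cell_volume
        Volume of one ECF cell (m³).
    coupling
        ``"plane_mean"`` (default): the flux into every cell of a plane is
        evaluated with the flow-weighted mean plasma concentration over
        that plane's capillary edges, keeping the ECF boundary data
        y-independent; the total plasma loss of the plane is distributed
        over its nodes in proportion to their current drug content.
        ``"per_node"``: the flux uses each cell's paired node concentration
        and the sink is applied to that node directly.

    Returns ``(ecf_source_west, ecf_source_east, plasma_sink, transfer)``:
    volumetric rates (μmol·m⁻³·s⁻¹) for the ECF boundary cells and every
    plasma node, plus the net blood→ECF transfer rate (μmol·s⁻¹).  The
    construction is conservative: transfer equals both the summed ECF gain
    and the summed plasma loss exactly.
    """
    plasma_sink = np.zeros_like(mu)
    ecf_sources = []
    transfer = 0.0
    for plane, rho_face in ((0, rho_west), (1, rho_east)):
        nodes = plan.plane_nodes[plane]
        if coupling == "plane_mean":
            node_set = plan.plane_node_sets[plane]
            vols = plan.plasma_volumes[node_set]
            mu_plane = float(np.sum(vols * mu[node_set]) / np.sum(vols))
            flux = bbb_flux(np.full_like(rho_face, mu_plane), rho_face,
                            params).total_flux
        elif coupling == "per_node":
            flux = bbb_flux(mu[nodes], rho_face, params).total_flux
        else:
            raise ValueError(f"unknown coupling '{coupling}'")
        cell_gain = flux * plan.face_area              # μmol/s per cell
        ecf_sources.append(cell_gain / ecf_cell_volume)
        plane_total = float(np.sum(cell_gain))
        transfer += plane_total
        if coupling == "plane_mean":
            node_set = plan.plane_node_sets[plane]
            vols = plan.plasma_volumes[node_set]
            content = vols * mu[node_set]
            total_content = float(np.sum(content))
            if plane_total >= 0 and total_content > 0:
                share = content / total_content
            else:
                share = vols / np.sum(vols)
            plasma_sink[node_set] -= plane_total * share / vols
        else:
            np.subtract.at(plasma_sink, nodes, cell_gain / plan.plasma_volumes[nodes])
    return ecf_sources[0], ecf_sources[1], plasma_sink, transfer
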