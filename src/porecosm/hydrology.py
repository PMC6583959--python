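"""Aqueous-phase configuration of an angular pore network at a prescribed
matric potential.

Under suction (matric potential Psi < 0) the liquid retreats into the pore
corners behind circular menisci of radius R = sigma/|Psi| (Young-Laplace,
zero contact angle).  Each corner of half-angle gamma/2 then holds a
cross-sectional water area

    A_corner = (sigma/Psi)^2 * [cot(gamma/2) - (pi/2 - gamma_rad/2)]

and the total corner water in a pore is capped at the pore area A_t.  A pore
actually drains only if an air path exists: it must be connected, through
other drainable pores, to an air interface at a declared boundary — trapped
air is not modelled, so enclosed candidate pores are forced saturated.

The thinnest corner film in a pore limits flagellated motility; its
thickness (diameter of the circle inscribed between wall and meniscus) is

    WFT = 2 * (sigma/|Psi|) * (1 - sin(gamma/2)) / (1 + sin(gamma/2)).

Conventions: Psi is stored negative (Pa); Psi = 0 means saturation by
definition; angles are degrees at the API and converted internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .network import PoreNetwork

__all__ = [
    "HydrationState",
    "corner_water_area",
    "pore_water_area",
    "film_thickness",
    "classify_saturation",
    "node_volumes",
    "retention_curve",
    "millington_quirk",
]

#: Water surface tension, N m^-1, at ~20 degC.
DEFAULT_SIGMA = 0.072


def corner_water_area(psi: float, gamma_i: float, sigma: float = DEFAULT_SIGMA) -> float:
    """Water-filled cross-sectional area (m^2) held in one corner of angle
    ``gamma_i`` (degrees) at matric potential ``psi`` (Pa, < 0)."""
    if psi >= 0:
        raise ValueError("corner_water_area requires psi < 0 (saturation is the caller's cap)")
    if not 0.0 < gamma_i < 180.0:
        raise ValueError(f"corner angle must be in (0, 180) deg, got {gamma_i}")
    half = math.radians(gamma_i) / 2.0
    bracket = 1.0 / math.tan(half) - (math.pi / 2.0 - half)
    return (sigma / psi) ** 2 * bracket


def pore_water_area(psi: float, geom, sigma: float = DEFAULT_SIGMA) -> float:
    """Total water-filled area of a pore: sum of corner areas capped at A_t.

    ``psi = 0`` returns the full cross-section (saturated).
    """
    if psi > 0:
        raise ValueError("matric potential is stored as a non-positive number")
    a_t = geom.total_area
    if psi == 0:
        return a_t
    total = sum(corner_water_area(psi, g, sigma) for g in geom.corner_angles)
    return min(total, a_t)


def film_thickness(psi: float, gamma_i: float, sigma: float = DEFAULT_SIGMA) -> float:
    """Corner water film thickness (m): the diameter of the largest circle
    inscribed between the liquid-air meniscus and the pore walls of a corner
    of angle ``gamma_i`` degrees."""
    if psi >= 0:
        raise ValueError("film thickness is unbounded at saturation (psi must be < 0)")
    if not 0.0 < gamma_i < 180.0:
        raise ValueError(f"corner angle must be in (0, 180) deg, got {gamma_i}")
    s = math.sin(math.radians(gamma_i) / 2.0)
    return 2.0 * (sigma / abs(psi)) * (1.0 - s) / (1.0 + s)


@dataclass
class HydrationState:
    """Per-pore and per-node aqueous state at one matric potential."""

    psi: float
    sigma: float
    water_area: np.ndarray  # (M,) m^2
    film: np.ndarray  # (M,) m; inf for saturated pores
    saturated: np.ndarray  # (M,) bool
    node_water_volume: np.ndarray  # (N,) m^3

    @property
    def saturation_fraction(self) -> float:
        """Water volume over pore volume; weights follow pore volumes."""
        # stored on assignment by classify_saturation
        return self._saturation_fraction

    def water_volume_total(self) -> float:
        return float(self.node_water_volume.sum())


def _uncapped_areas(network: PoreNetwork, psi: float, sigma: float) -> np.ndarray:
    out = np.empty(network.n_pores)
    for j, g in enumerate(network.geometries):
        out[j] = sum(corner_water_area(psi, a, sigma) for a in g.corner_angles)
    return out


def classify_saturation(
    network: PoreNetwork,
    psi: float,
    sigma: float = DEFAULT_SIGMA,
    air_boundary: str = "periphery",
) -> HydrationState:
    """Compute the full hydration state of a network at ``psi``.

    A pore is unsaturated iff (a) its uncapped corner-water sum is below its
    total area and (b) a continuous path of such pores connects it to an air
    interface at a node of the ``air_boundary`` set.  All other pores take
    A_w = A_t (trapped air collapses to saturation).  Per-pore film
    thickness is the minimum over corners; saturated pores carry +inf (no
    film restriction on motility).
    """
    a_t = network.total_areas
    if psi == 0:
        a_w = a_t.copy()
        sat = np.ones(network.n_pores, dtype=bool)
        film = np.full(network.n_pores, np.inf)
    else:
        uncapped = _uncapped_areas(network, psi, sigma)
        candidate = uncapped < a_t
        air_nodes = network.boundary_sets.get(air_boundary)
        if air_nodes is None or len(air_nodes) == 0:
            warnings.warn(
                f"no air-access boundary {air_boundary!r} declared: all pores "
                "treated as saturated",
                stacklevel=2,
            )
            reachable = np.zeros(network.n_pores, dtype=bool)
        else:
            reachable = _air_connected(network, candidate, air_nodes)
        sat = ~reachable
        a_w = np.where(sat, a_t, uncapped)
        film = np.full(network.n_pores, np.inf)
        for j, g in enumerate(network.geometries):
            if not sat[j]:
                film[j] = min(film_thickness(psi, a, sigma) for a in g.corner_angles)
    state = HydrationState(
        psi=psi,
        sigma=sigma,
        water_area=a_w,
        film=film,
        saturated=sat,
        node_water_volume=node_volumes(network, a_w),
    )
    vol = network.pore_volumes()
    state._saturation_fraction = float((a_w * network.lengths).sum() / vol.sum())
    return state


def _air_connected(
    network: PoreNetwork, candidate: np.ndarray, air_nodes: np.ndarray
) -> np.ndarray:
    """BFS over candidate pores seeded at pores touching an air node."""
    ptr, pidx, _ = network.incidence()
    air = np.zeros(network.n_nodes, dtype=bool)
    air[air_nodes] = True
    touches_air = air[network.pores[:, 0]] | air[network.pores[:, 1]]
    frontier = list(np.flatnonzero(candidate & touches_air))
    seen = np.zeros(network.n_pores, dtype=bool)
    seen[frontier] = True
    while frontier:
        j = frontier.pop()
        for n in network.pores[j]:
            for k in pidx[ptr[n]: ptr[n + 1]]:
                if candidate[k] and not seen[k]:
                    seen[k] = True
                    frontier.append(k)
    return seen


def node_volumes(network: PoreNetwork, water_area: np.ndarray) -> np.ndarray:
    """Water volume attributed to each node: half of every incident pore,
    V_w(n) = sum_j A_w,j * L_j / 2."""
    half = np.asarray(water_area) * network.lengths / 2.0
    vol = np.zeros(network.n_nodes)
    np.add.at(vol, network.pores[:, 0], half)
    np.add.at(vol, network.pores[:, 1], half)
    return vol


def retention_curve(
    network: PoreNetwork,
    psi_grid,
    sigma: float = DEFAULT_SIGMA,
    air_boundary: str = "periphery",
) -> np.ndarray:
    """Degree of saturation sum(A_w L)/sum(A_t L) at each potential of
    ``psi_grid`` (Pa, non-positive)."""
    return np.array(
        [
            classify_saturation(network, float(p), sigma, air_boundary).saturation_fraction
            for p in psi_grid
        ]
    )


def millington_quirk(theta: float, phi: float) -> float:
    """Relative effective diffusivity (saturated value = 1) of a porous
    medium at volumetric water content ``theta`` and porosity ``phi``,
    after the Millington-Quirk model D_e/D_0 = theta^(10/3)/phi^2; the
    normalisation by the saturated value leaves (theta/phi)^(10/3)."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"porosity must be in [0, 1], got {phi}")
    if theta < 0 or theta > phi:
        raise ValueError(f"water content {theta} outside [0, porosity={phi}]")
    if phi == 0:
        return 0.0
    return float((theta / phi) ** (10.0 / 3.0))
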