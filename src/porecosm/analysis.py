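"""Spatial and temporal summaries of simulation outputs."""

from __future__ import annotations

import numpy as np

from .network import PoreNetwork

__all__ = [
    "node_radii",
    "center_of_mass_radius",
    "radial_band_fractions",
    "pulse_response",
]


def node_radii(network: PoreNetwork) -> tuple[np.ndarray, float]:
    """Distance of every node from the domain centroid, and the maximum."""
    center = network.node_coordinates.mean(axis=0)
    r = np.hypot(*(network.node_coordinates - center).T)
    return r, float(r.max())


def center_of_mass_radius(network: PoreNetwork, node_values: np.ndarray) -> float:
    """Value-weighted mean radial position, normalised by the domain radius."""
    r, r_max = node_radii(network)
    total = node_values.sum()
    if total <= 0:
        return float("nan")
    return float((r * node_values).sum() / total / r_max)


def radial_band_fractions(
    network: PoreNetwork, node_values: np.ndarray, edges=(1 / 3, 2 / 3)
) -> np.ndarray:
    """Fraction of the summed value inside each radial band of r/R."""
    r, r_max = node_radii(network)
    rel = r / r_max
    bounds = (0.0, *edges, 1.0 + 1e-9)
    total = node_values.sum()
    out = np.zeros(len(bounds) - 1)
    for i in range(len(out)):
        mask = (rel >= bounds[i]) & (rel < bounds[i + 1])
        out[i] = node_values[mask].sum() / total if total > 0 else np.nan
    return out


def pulse_response(times: np.ndarray, biomass: np.ndarray, pulse_time: float):
    """(plateau, peak, peak_time, final) of a perturbation experiment:
    plateau is the biomass just before the pulse, peak the post-pulse
    maximum."""
    i = int(np.searchsorted(times, pulse_time))
    i = max(1, min(i, len(times) - 1))
    plateau = float(biomass[i - 1])
    j = i + int(np.argmax(biomass[i:]))
    return plateau, float(biomass[j]), float(times[j]), float(biomass[-1])
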