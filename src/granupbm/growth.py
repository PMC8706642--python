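"""Continuous single-granule rate processes.

Four mechanisms act on existing granules between collisions: rewetting
(spray liquid landing on granule surfaces in proportion to their
volume), excipient layering (fine hydrophilic powder adhering to wet
surfaces), surface growth (solid-spread marbles smearing their API shell
onto granules large enough to rupture them on impact) and consolidation
(collision-driven compaction that squeezes pores shut and can expel
internal liquid to the surface).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .aggregation import granular_velocity, marble_rupture_threshold
from .config import MaterialSet, ProcessConditions
from .grid_state import GranuleEnsemble, move_cells
from .nucleation import NucleusSpec

__all__ = [
    "rewetting_rates",
    "layering_rates",
    "surface_growth_rates",
    "consolidation_step",
    "SurfaceGrowthRates",
]


def rewetting_rates(ensemble: GranuleEnsemble, q_rewet: float):
    """External-liquid deposition rates, proportional to F * v per cell.

    Returns ``(dLe_dt, returned)``: the per-cell total-liquid rate array
    summing exactly to ``q_rewet``, and the flow returned to the
    reservoir when no granules exist to receive it.
    """
    dle = np.zeros_like(ensemble.F)
    if q_rewet <= 0:
        return dle, 0.0
    idx = ensemble.occupied()
    if len(idx[0]) == 0:
        return dle, q_rewet
    props = ensemble.cell_properties(idx)
    weight = props["F"] * props["v"]
    total = weight.sum()
    if total <= 0:
        return dle, q_rewet
    dle[idx] = q_rewet * weight / total
    return dle, 0.0


def layering_rates(ensemble: GranuleEnsemble, ms2: float, k_layer: float,
                   rho_s2: float):
    """Excipient layering: ds2/dt = k_layer * a * Ms2 / rho_s2 on wet cells.

    Only granules with surface wetness (per-particle le > 0) layer; the
    excipient reservoir is depleted mass-consistently.  Returns the
    per-particle rate array (m3/s) and dMs2/dt (kg/s, non-positive).
    """
    ds2 = np.zeros_like(ensemble.F)
    if ms2 <= 0 or k_layer <= 0:
        return ds2, 0.0
    idx = ensemble.occupied()
    if len(idx[0]) == 0:
        return ds2, 0.0
    props = ensemble.cell_properties(idx)
    wet = props["le"] > 0
    rate = np.where(wet, k_layer * props["a"] * ms2 / rho_s2, 0.0)
    ds2[idx] = rate
    dms2 = -rho_s2 * float((props["F"] * rate).sum())
    return ds2, dms2


@dataclass
class SurfaceGrowthRates:
    """Rates of API deposition from the solid-spread marble reservoir."""

    ds1_dt: np.ndarray          # per-particle API volume rate, m3/s
    marble_rate: float          # marbles consumed per second
    le_credit: np.ndarray       # external liquid delivered per cell, m3/s
    d_threshold: float          # minimum receiving granule diameter, m


def surface_growth_rates(ensemble: GranuleEnsemble, k_sg: float,
                         materials: MaterialSet, process: ProcessConditions,
                         spec: NucleusSpec,
                         theta_prefactor: float = 5.0 * math.pi / 96.0
                         ) -> SurfaceGrowthRates:
    """API surface growth onto granules above the marble-rupture size.

    A marble of diameter D spreads to D_max = D (1 + 0.12 We) on impact;
    only granules at least that large rupture it and collect the shell:
    ds1/dt = k_sg v^(2/3) there.  The API comes from the marble class
    (with its booked per-marble API volume) and each consumed marble
    releases its drop to the receiving cells' surface liquid.
    """
    zeros = np.zeros_like(ensemble.F)
    d_max = marble_rupture_threshold(materials, process, spec, theta_prefactor)
    out = SurfaceGrowthRates(ds1_dt=zeros, marble_rate=0.0,
                             le_credit=zeros.copy(), d_threshold=d_max)
    if ensemble.Fss <= 0 or k_sg <= 0:
        return out
    api_per_marble = ensemble.ss_api_volume / ensemble.Fss
    drop_per_marble = ensemble.ss_drop_volume / ensemble.Fss
    if api_per_marble <= 0:
        return out
    idx = ensemble.occupied()
    if len(idx[0]) == 0:
        return out
    props = ensemble.cell_properties(idx)
    eligible = props["d"] >= d_max
    if not eligible.any():
        return out
    rate = np.where(eligible, k_sg * props["v"] ** (2.0 / 3.0), 0.0)
    out.ds1_dt[idx] = rate
    delivered = props["F"] * rate
    out.marble_rate = float(delivered.sum()) / api_per_marble
    out.le_credit[idx] = delivered * (drop_per_marble / api_per_marble)
    return out


def consolidation_step(ensemble: GranuleEnsemble, k_con: float, eps_min: float,
                       process: ProcessConditions, dt: float,
                       theta_prefactor: float = 5.0 * math.pi / 96.0) -> None:
    """One compaction step: porosity decays toward eps_min, in place.

    d_eps = k_con * U * dt * (eps - eps_min), applied only where the
    result stays at or above eps_min; the collision velocity U is the
    granular-temperature relative velocity at the cell's diameter.  Pore
    volume is re-closed from the new porosity at fixed solids and
    surface liquid; internal liquid that no longer fits the pores is
    squeezed out to the surface.
    """
    if k_con <= 0 or dt <= 0:
        return
    idx = ensemble.occupied()
    if len(idx[0]) == 0:
        return
    props = ensemble.cell_properties(idx)
    eps = props["p"] / props["v"]
    u = granular_velocity(process.gamma, props["d"], process.phi_p,
                          theta_prefactor)
    d_eps = k_con * u * dt * np.maximum(eps - eps_min, 0.0)
    d_eps = np.where(eps - d_eps >= eps_min, d_eps, 0.0)
    if not (d_eps > 0).any():
        return
    eps_new = eps - d_eps
    solids = props["s1"] + props["s2"] + props["le"]
    p_new = eps_new / (1.0 - eps_new) * solids
    p_new = np.where(d_eps > 0, p_new, props["p"])
    targets = np.column_stack([props["s1"], props["s2"], p_new])
    move_cells(ensemble, idx, targets)
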