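"""Pairwise aggregation: collision efficiency, merge rule and rates.

The aggregation kernel is beta = beta0 * beta*, with beta* the physics-
based collision efficiency: the ratio of the work done by capillary and
viscous forces in the liquid bridge to the pair's kinetic energy,
clipped to [0, 1].  The merged granule interpolates between two
deformability extremes: hard elastic collisions conserve surface area
(sticking, extra void created) and soft plastic collisions conserve pore
volume (deformation, volumes additive); the interpolation weight is the
pair softness zeta = 1 - e_coag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import KernelOptions, MaterialSet, ProcessConditions, RateConstants
from .grid_state import (GranuleEnsemble, InvalidStateError, diameter_from_volume,
                         surface_area)
from .nucleation import NucleusSpec

__all__ = [
    "granule_restitution",
    "restitution_pair",
    "granular_velocity",
    "dissipative_work",
    "capillary_number",
    "capillary_work",
    "collision_efficiency",
    "combine_granules",
    "aggregation_step",
    "AggregationRates",
]

_SQRT_PI6 = 6.0 * math.sqrt(math.pi)


def granule_restitution(s1, s2, rho_s1, rho_s2, e_s1, e_s2):
    """Mass-weighted coefficient of restitution of a granule.

    The pore phase carries zero mass and zero restitution, so only the
    two solid components contribute.
    """
    m1 = rho_s1 * np.asarray(s1, dtype=float)
    m2 = rho_s2 * np.asarray(s2, dtype=float)
    total = m1 + m2
    if np.any(total <= 0):
        raise InvalidStateError("granule restitution undefined for zero solid mass")
    return (e_s1 * m1 + e_s2 * m2) / total


def restitution_pair(s1_a, s2_a, s1_b, s2_b, materials: MaterialSet):
    """Per-granule restitutions, pair restitution and softness.

    Returns (e_A, e_B, e_coag, zeta) with e_coag = e_A e_B and
    zeta = 1 - e_coag in [0, 1].
    """
    e_a = granule_restitution(s1_a, s2_a, materials.rho_s1, materials.rho_s2,
                              materials.e_s1, materials.e_s2)
    e_b = granule_restitution(s1_b, s2_b, materials.rho_s1, materials.rho_s2,
                              materials.e_s1, materials.e_s2)
    e_coag = e_a * e_b
    return e_a, e_b, e_coag, 1.0 - e_coag


def _volume_fraction_factor(phi_p: float) -> float:
    # dense-flow closure g(phi_p); only Theta ~ gamma^2 d^2 is load-bearing
    return 1.0 / (12.0 * phi_p ** 2 * (1.0 - phi_p) * (1.0 - phi_p ** 2))


def granular_velocity(gamma: float, d, phi_p: float,
                      theta_prefactor: float = 5.0 * math.pi / 96.0):
    """Mean relative collision velocity from the granular temperature.

    Theta = C * gamma^2 d^2 * g(phi_p), v_r = sqrt(32 Theta / pi);
    homogeneous of degree one in both the shear rate and the diameter.
    """
    if gamma <= 0:
        raise InvalidStateError("shear rate must be positive")
    if not 0.0 < phi_p < 1.0:
        raise InvalidStateError("phi_p must lie in (0, 1)")
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise InvalidStateError("diameter must be positive")
    theta = theta_prefactor * gamma ** 2 * d ** 2 * _volume_fraction_factor(phi_p)
    return np.sqrt(32.0 * theta / math.pi)


def dissipative_work(d_tilde, mu: float, e_coag, v_r, h, h_a: float):
    """Viscous (lubrication) work of the liquid bridge.

    W_d = (3 pi mu d~^2 e_coag v_r / 4) ln(h / h_a); zero when the binder
    layer is thinner than the surface asperities (no bridge forms).
    """
    d_tilde = np.asarray(d_tilde, dtype=float)
    h = np.asarray(h, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.where(h > h_a, np.log(np.maximum(h, h_a) / h_a), 0.0)
    return 3.0 * math.pi * mu * d_tilde ** 2 * np.asarray(e_coag) * np.asarray(v_r) / 4.0 * logterm


def capillary_number(f_api, anchors) -> np.ndarray:
    """Log-linear capillary-number regression through two anchor points.

    ``anchors`` is ((f_lo, Ca_lo), (f_hi, Ca_hi)); the returned Ca(f) is
    the formulation-dependent ratio of capillary to viscous bridge force.
    """
    (f0, c0), (f1, c1) = anchors
    if c0 <= 0 or c1 <= 0 or f0 == f1:
        raise InvalidStateError("anchors must have distinct f and positive Ca")
    slope = (math.log(c1) - math.log(c0)) / (f1 - f0)
    f = np.asarray(f_api, dtype=float)
    return np.exp(math.log(c0) + slope * (f - f0))


def capillary_work(f_api, anchors, reference_visc_work):
    """Composition-dependent capillary work, W_c = Ca(f) * W_d."""
    ca = np.clip(capillary_number(f_api, anchors), 0.0, None)
    return ca * np.asarray(reference_visc_work, dtype=float)


def marble_rupture_threshold(materials: MaterialSet, process: ProcessConditions,
                             spec: NucleusSpec,
                             theta_prefactor: float = 5.0 * math.pi / 96.0) -> float:
    """Minimum granule diameter that ruptures a liquid marble on impact.

    The marble spreads to D_max = D (1 + 0.12 We) before rupturing;
    granules at least that large collect the API shell (surface growth),
    smaller ones merely bounce.
    """
    v_r = float(granular_velocity(process.gamma, spec.D_ss, process.phi_p,
                                  theta_prefactor))
    weber = materials.rho_l * v_r ** 2 * spec.D_ss / materials.sigma
    return spec.D_ss * (1.0 + 0.12 * weber)


def _pair_properties(a: dict, b: dict, materials: MaterialSet,
                     process: ProcessConditions):
    """Derived pair quantities shared by the efficiency and the merge."""
    e_a, e_b, e_coag, zeta = restitution_pair(a["s1"], a["s2"], b["s1"], b["s2"],
                                              materials)
    d_tilde = 2.0 * a["d"] * b["d"] / (a["d"] + b["d"])
    m_a = materials.rho_s1 * a["s1"] + materials.rho_s2 * a["s2"] \
        + materials.rho_l * (a["le"] + a["li"])
    m_b = materials.rho_s1 * b["s1"] + materials.rho_s2 * b["s2"] \
        + materials.rho_l * (b["le"] + b["li"])
    m = 2.0 * m_a * m_b / (m_a + m_b)
    h = 0.5 * (a["le"] / a["a"] + b["le"] / b["a"])
    solids = a["s1"] + b["s1"] + a["s2"] + b["s2"]
    f_api = (a["s1"] + b["s1"]) / solids
    return e_coag, zeta, d_tilde, m, h, f_api


def collision_efficiency(a: dict, b: dict, materials: MaterialSet,
                         process: ProcessConditions,
                         kernel: KernelOptions):
    """Collision efficiency beta* in [0, 1] for property dicts A, B.

    Each dict holds per-particle arrays s1, s2, p, le, li, v, a, d.
    beta* = min(1, (W_c + W_d) / E_k); contacts with vanishing kinetic
    energy always stick.
    """
    if kernel.efficiency_mode == "unit":
        return np.ones_like(np.asarray(a["v"], dtype=float))
    e_coag, _, d_tilde, m, h, f_api = _pair_properties(a, b, materials, process)
    v_r = granular_velocity(process.gamma, d_tilde, process.phi_p,
                            kernel.theta_prefactor)
    w_d = dissipative_work(d_tilde, materials.mu, e_coag, v_r, h, materials.h_a)
    w_c = capillary_work(f_api, kernel.ca_anchors, w_d)
    e_k = 0.5 * m * e_coag ** 2 * v_r ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(e_k > 0, (w_c + w_d) / np.where(e_k > 0, e_k, 1.0), 1.0)
    return np.clip(ratio, 0.0, 1.0)


def combine_granules(a: dict, b: dict, zeta):
    """Merge two granules into one; returns the combined property dict.

    Solids are additive.  External liquid is partially drawn into the new
    internal volume (geometric-mean transfer with overlap caps).  The new
    envelope volume interpolates between pore-conserving (zeta = 1) and
    area-conserving (zeta = 0) extremes; the pore volume closes the
    volume balance and internal liquid is squeezed back out if it would
    exceed the pores.
    """
    zeta = np.asarray(zeta, dtype=float)
    if np.any(zeta < 0) or np.any(zeta > 1):
        raise InvalidStateError("zeta must lie in [0, 1]")
    s1 = a["s1"] + b["s1"]
    s2 = a["s2"] + b["s2"]
    le_sum = a["le"] + b["le"]
    li_sum = a["li"] + b["li"]

    cbrt_sum = np.cbrt(a["v"]) + np.cbrt(b["v"])

    def overlap_factor(g):
        r = np.clip(np.cbrt(np.maximum(g["v"] - g["le"], 0.0)) / cbrt_sum, 0.0, 1.0)
        return 1.0 - np.sqrt(np.clip(1.0 - r ** 2, 0.0, 1.0))

    l_ei = np.sqrt(a["le"] * b["le"]) * overlap_factor(a) * overlap_factor(b)
    l_ei = np.minimum(l_ei, le_sum)
    le = le_sum - l_ei
    li = li_sum + l_ei

    v = zeta * (a["v"] + b["v"]) + (1.0 - zeta) * (a["a"] + b["a"]) ** 1.5 / _SQRT_PI6
    p = v - s1 - s2 - le
    # squeeze internal liquid back to the surface if pores cannot hold it
    excess = np.maximum(li - p, 0.0)
    le = le + excess
    li = li - excess
    v = s1 + s2 + le + np.maximum(p, 0.0)
    p = np.maximum(p, 0.0)
    return {"s1": s1, "s2": s2, "p": p, "le": le, "li": li, "v": v,
            "a": surface_area(v), "d": diameter_from_volume(v)}


@dataclass
class AggregationRates:
    """Per-cell formation/depletion rates ready for an Euler update.

    ``form_*`` already include the cell-average splitting of the merged
    granules; ``dep_*`` remove the colliding partners and their average
    liquid.  Marble-class (solid-spread nuclei) self-aggregation rates
    are scalars.
    """

    form_F: np.ndarray
    form_Le: np.ndarray
    form_Li: np.ndarray
    dep_F: np.ndarray
    dep_Le: np.ndarray
    dep_Li: np.ndarray
    dFss: float = 0.0
    dss_api: float = 0.0
    dss_drop: float = 0.0
    ledger_rates: dict = field(default_factory=lambda: {"s1": 0.0, "s2": 0.0, "p": 0.0})

    def max_outflow_fraction_time(self, ensemble: GranuleEnsemble) -> float:
        """Smallest F / outflow over cells (inf if no outflow)."""
        times = [np.inf]
        mask = self.dep_F > 0
        if mask.any():
            times.append(float((ensemble.F[mask] / self.dep_F[mask]).min()))
        if self.dFss > 0 and ensemble.Fss > 0:
            times.append(ensemble.Fss / self.dFss)
        return min(times)

    def apply(self, ensemble: GranuleEnsemble, dt: float) -> float:
        """Euler-update the ensemble; returns the rescale factor used.

        If the fixed step would drive any cell count negative (the rates
        were assembled from a slightly earlier sub-step state), the whole
        rate set is scaled down uniformly, which preserves all the
        conservation properties of the pair loop.
        """
        scale = 1.0
        mask = self.dep_F > 0
        if mask.any():
            headroom = float((ensemble.F[mask] / (dt * self.dep_F[mask])).min())
            scale = min(scale, headroom)
        if self.dFss > 0 and ensemble.Fss >= 0:
            scale = min(scale, ensemble.Fss / (dt * self.dFss))
        scale = max(0.0, min(1.0, scale))
        dt = dt * scale
        ensemble.F += dt * (self.form_F - self.dep_F)
        ensemble.Le += dt * (self.form_Le - self.dep_Le)
        ensemble.Li += dt * (self.form_Li - self.dep_Li)
        ensemble.Fss -= dt * self.dFss
        ensemble.ss_api_volume -= dt * self.dss_api
        ensemble.ss_drop_volume -= dt * self.dss_drop
        for k, v in self.ledger_rates.items():
            ensemble.ledger[k] += dt * v
        np.clip(ensemble.F, 0.0, None, out=ensemble.F)
        np.clip(ensemble.Le, 0.0, None, out=ensemble.Le)
        np.clip(ensemble.Li, 0.0, None, out=ensemble.Li)
        ensemble.Fss = max(ensemble.Fss, 0.0)
        ensemble.ss_api_volume = max(ensemble.ss_api_volume, 0.0)
        ensemble.ss_drop_volume = max(ensemble.ss_drop_volume, 0.0)
        ensemble.enforce_saturation()
        return scale


def _deposit_rates(ensemble: GranuleEnsemble, targets, amounts, le_per, li_per,
                   form_F, form_Le, form_Li, ledger_rates) -> None:
    """Accumulate cell-average formation rates for merged granules."""
    grid = ensemble.grid
    n = grid.n_bins
    names = ("s1", "s2", "p")
    los, his, ws = [], [], []
    for c in range(3):
        lo, hi, w_lo, defect = grid.locate(targets[:, c])
        ledger_rates[names[c]] += float((defect * amounts).sum())
        los.append(lo)
        his.append(hi)
        ws.append(w_lo)
    m = len(amounts)
    flat_idx = np.empty(8 * m, dtype=np.intp)
    flat_w = np.empty(8 * m)
    for corner in range(8):
        bits = ((corner >> 0) & 1, (corner >> 1) & 1, (corner >> 2) & 1)
        w = np.ones(m)
        ii = []
        for c, bit in enumerate(bits):
            w = w * (ws[c] if bit == 0 else (1.0 - ws[c]))
            ii.append(los[c] if bit == 0 else his[c])
        sl = slice(corner * m, (corner + 1) * m)
        flat_idx[sl] = (ii[0] * n + ii[1]) * n + ii[2]
        flat_w[sl] = w
    dep = np.tile(amounts, 8) * flat_w
    size = n ** 3
    form_F += np.bincount(flat_idx, weights=dep, minlength=size).reshape(form_F.shape)
    form_Le += np.bincount(flat_idx, weights=dep * np.tile(le_per, 8),
                           minlength=size).reshape(form_F.shape)
    form_Li += np.bincount(flat_idx, weights=dep * np.tile(li_per, 8),
                           minlength=size).reshape(form_F.shape)


def _select(props: dict, take) -> dict:
    return {k: v[take] for k, v in props.items()}


def aggregation_step(ensemble: GranuleEnsemble, rates: RateConstants,
                     materials: MaterialSet, process: ProcessConditions,
                     kernel: KernelOptions, pair_threshold: float = 0.0,
                     spec: NucleusSpec = None,
                     chunk: int = 200_000) -> AggregationRates:
    """Assemble aggregation rate fields from a symmetric pair loop.

    All occupied cells above ``pair_threshold`` (relative to total
    number) participate; self-pairs use the F(F-1)/2 count.  Solid-spread
    marbles take part through two channels: marble-marble coalescence
    (the merged pair enters the granule phase with its drops as external
    liquid) and, when ``spec`` is given, marble-granule surface transfer
    (collisions with granules above the rupture size deposit the API
    shell and the drop onto the granule without changing its count).
    """
    shape = ensemble.F.shape
    out = AggregationRates(
        form_F=np.zeros(shape), form_Le=np.zeros(shape), form_Li=np.zeros(shape),
        dep_F=np.zeros(shape), dep_Le=np.zeros(shape), dep_Li=np.zeros(shape),
    )
    if rates.beta0 <= 0:
        return out
    idx = ensemble.occupied(pair_threshold)
    m = len(idx[0])
    if m > 0:
        props = ensemble.cell_properties(idx)
        iu, ju = np.triu_indices(m, k=0)
        for start in range(0, len(iu), chunk):
            sl = slice(start, start + chunk)
            _accumulate_pairs(ensemble, props, idx, iu[sl], ju[sl], rates,
                              materials, process, kernel, out)
        if spec is not None:
            _marble_granule(ensemble, props, idx, rates, materials, process,
                            kernel, spec, out)
    _marble_pair(ensemble, rates, materials, process, kernel, out)
    return out


def kernel_diagnostics(ensemble: GranuleEnsemble, materials: MaterialSet,
                       process: ProcessConditions, kernel: KernelOptions,
                       pair_threshold: float = 0.0,
                       max_cells: int = 64) -> pd.DataFrame:
    """Pairwise collision-efficiency table for inspection.

    Returns one row per occupied-cell pair (capped at the ``max_cells``
    most populated cells) with both cells' indices, diameters and the
    efficiency beta*.
    """
    idx = ensemble.occupied(pair_threshold)
    if len(idx[0]) == 0:
        return pd.DataFrame(columns=["i_a", "j_a", "k_a", "i_b", "j_b", "k_b",
                                     "d_a", "d_b", "beta_star"])
    props = ensemble.cell_properties(idx)
    order = np.argsort(props["F"])[::-1][:max_cells]
    idx = tuple(ax[order] for ax in idx)
    props = _select(props, order)
    m = len(order)
    iu, ju = np.triu_indices(m, k=0)
    a = _select(props, iu)
    b = _select(props, ju)
    beta_star = collision_efficiency(a, b, materials, process, kernel)
    return pd.DataFrame({
        "i_a": idx[0][iu], "j_a": idx[1][iu], "k_a": idx[2][iu],
        "i_b": idx[0][ju], "j_b": idx[1][ju], "k_b": idx[2][ju],
        "d_a": a["d"], "d_b": b["d"], "beta_star": beta_star,
    })


def _marble_state(ensemble):
    if ensemble.Fss <= 0:
        return None
    s1m = ensemble.ss_api_volume / ensemble.Fss
    lem = ensemble.ss_drop_volume / ensemble.Fss
    if s1m <= 0:
        return None
    v = s1m + lem
    return {
        "s1": np.array([s1m]), "s2": np.array([0.0]), "p": np.array([0.0]),
        "le": np.array([lem]), "li": np.array([0.0]), "v": np.array([v]),
        "a": surface_area(np.array([v])), "d": diameter_from_volume(np.array([v])),
    }


def _marble_granule(ensemble, props, idx, rates, materials, process, kernel,
                    spec, out) -> None:
    """Marble rupture on large granules: the surface-growth collision channel."""
    marble = _marble_state(ensemble)
    if marble is None:
        return
    d_max = marble_rupture_threshold(materials, process, spec,
                                     kernel.theta_prefactor)
    eligible = np.nonzero(props["d"] >= d_max)[0]
    if len(eligible) == 0:
        return
    g = _select(props, eligible)
    nb = len(eligible)
    mb = {k: np.broadcast_to(v, (nb,)) for k, v in marble.items()}
    beta_star = collision_efficiency(mb, g, materials, process, kernel)
    events = rates.beta0 * beta_star * ensemble.Fss * g["F"]
    live = events > 0
    if not live.any():
        return
    events = events[live]
    g = _select(g, live)
    sel = tuple(ax[eligible[live]] for ax in idx)
    s1m = float(marble["s1"][0])
    lem = float(marble["le"][0])
    np.add.at(out.dep_F, sel, events)
    np.add.at(out.dep_Le, sel, events * g["le"])
    np.add.at(out.dep_Li, sel, events * g["li"])
    targets = np.column_stack([g["s1"] + s1m, g["s2"], g["p"]])
    _deposit_rates(ensemble, targets, events, g["le"] + lem, g["li"],
                   out.form_F, out.form_Le, out.form_Li, out.ledger_rates)
    total = float(events.sum())
    out.dFss += total
    out.dss_api += total * s1m
    out.dss_drop += total * lem


def _accumulate_pairs(ensemble, props, idx, iu, ju, rates, materials, process,
                      kernel, out) -> None:
    a = _select(props, iu)
    b = _select(props, ju)
    if kernel.efficiency_mode == "unit":
        beta_star = np.ones(len(iu))
        _, _, _, zeta = restitution_pair(a["s1"], a["s2"], b["s1"], b["s2"],
                                         materials)
    else:
        e_coag, zeta, d_tilde, m, h, f_api = _pair_properties(a, b, materials,
                                                              process)
        v_r = granular_velocity(process.gamma, d_tilde, process.phi_p,
                                kernel.theta_prefactor)
        w_d = dissipative_work(d_tilde, materials.mu, e_coag, v_r, h,
                               materials.h_a)
        w_c = capillary_work(f_api, kernel.ca_anchors, w_d)
        e_k = 0.5 * m * e_coag ** 2 * v_r ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(e_k > 0, (w_c + w_d) / np.where(e_k > 0, e_k, 1.0),
                             1.0)
        beta_star = np.clip(ratio, 0.0, 1.0)
    self_pair = iu == ju
    counts = np.where(self_pair,
                      np.maximum(a["F"] * (a["F"] - 1.0), 0.0) / 2.0,
                      a["F"] * b["F"])
    rate = rates.beta0 * beta_star * counts
    live = rate > 0
    if not live.any():
        return
    rate = rate[live]
    a = _select(a, live)
    b = _select(b, live)
    zeta = zeta[live] if np.ndim(zeta) else zeta
    iu, ju = iu[live], ju[live]

    n = ensemble.grid.n_bins
    size = n ** 3
    flat_a = (idx[0][iu] * n + idx[1][iu]) * n + idx[2][iu]
    flat_b = (idx[0][ju] * n + idx[1][ju]) * n + idx[2][ju]
    both = np.concatenate([flat_a, flat_b])
    shape = out.dep_F.shape
    out.dep_F += np.bincount(both, weights=np.tile(rate, 2),
                             minlength=size).reshape(shape)
    out.dep_Le += np.bincount(both, weights=np.concatenate([rate * a["le"],
                                                            rate * b["le"]]),
                              minlength=size).reshape(shape)
    out.dep_Li += np.bincount(both, weights=np.concatenate([rate * a["li"],
                                                            rate * b["li"]]),
                              minlength=size).reshape(shape)

    merged = combine_granules(a, b, zeta)
    targets = np.column_stack([merged["s1"], merged["s2"], merged["p"]])
    _deposit_rates(ensemble, targets, rate, merged["le"], merged["li"],
                   out.form_F, out.form_Le, out.form_Li, out.ledger_rates)


def _marble_pair(ensemble, rates, materials, process, kernel, out) -> None:
    """Marble-marble coalescence: two marbles merge into a bigger marble.

    The product is still a liquid marble, so it stays in the nuclei
    class: each event removes one from the count while the class volume
    totals are unchanged, growing the mean per-marble payload.  Marbles
    enter the granule phase only by rupturing on a granule.
    """
    if ensemble.Fss <= 1.0:
        return
    marble = _marble_state(ensemble)
    if marble is None:
        return
    beta_star = collision_efficiency(marble, marble, materials, process, kernel)[0]
    events = rates.beta0 * beta_star * ensemble.Fss * (ensemble.Fss - 1.0) / 2.0
    if events <= 0:
        return
    out.dFss += events
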