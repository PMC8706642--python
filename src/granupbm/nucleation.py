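"""Drop-to-nucleus conversion during the liquid-addition phase.

Sprayed binder drops either penetrate the powder bed and suck solids into
a saturated *immersion* nucleus, or — when the blend is rich in the
hydrophobic API — become *solid-spread* nuclei: liquid marbles coated by
a shell of API primary particles.  The split is governed by a
formulation-dependent immersion probability P_im(f1), decreasing with the
API mass fraction.  Nucleation kinetics are treated as instantaneous
within a time step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .config import (ConfigError, MaterialSet, NucleationOptions,
                     ProcessConditions)
from .grid_state import (BulkPhase, GranuleEnsemble, redistribute_cell_average,
                         volume_from_diameter)

__all__ = [
    "NucleationProbabilityProvider",
    "NucleusSpec",
    "nucleation_probability",
    "immersion_nucleus_volumes",
    "solid_spread_nucleus_volumes",
    "immersion_nucleation_step",
    "solid_spread_nucleation_step",
]


class NucleationProbabilityProvider:
    """Maps the blend API mass fraction to the immersion probability.

    Stands in for the upstream data-driven nucleation classifier: only
    the predicted probabilities enter the population balance, so any
    monotone surrogate anchored to the same probabilities is exchangeable
    with it.  Modes: ``constant``, ``logistic`` (least-squares logistic
    through anchor points, monotonically decreasing in f1) and ``table``
    (linear interpolation).
    """

    def __init__(self, options: NucleationOptions | None = None):
        self.options = options or NucleationOptions()
        mode = self.options.mode
        if mode == "constant":
            p = float(self.options.constant)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"constant P_im must lie in [0, 1], got {p}")
            self._fn = lambda f1: np.full_like(np.asarray(f1, dtype=float), p)
        elif mode == "logistic":
            anchors = np.asarray(self.options.anchors, dtype=float)
            self._check_anchors(anchors)
            f, p = anchors[:, 0], anchors[:, 1]

            def resid(theta):
                k, f0 = theta
                return 1.0 / (1.0 + np.exp(k * (f - f0))) - p

            sol = least_squares(resid, x0=[10.0, 0.5], bounds=([1e-3, 0.0], [200.0, 1.0]))
            k, f0 = sol.x
            self._fn = lambda f1: 1.0 / (1.0 + np.exp(k * (np.asarray(f1, dtype=float) - f0)))
            self.k_, self.f0_ = float(k), float(f0)
        elif mode == "table":
            if not self.options.table:
                raise ConfigError("table mode requires a (f1, P_im) table")
            anchors = np.asarray(self.options.table, dtype=float)
            self._check_anchors(anchors)
            order = np.argsort(anchors[:, 0])
            f, p = anchors[order, 0], anchors[order, 1]
            self._fn = lambda f1: np.interp(np.asarray(f1, dtype=float), f, p)
        else:  # pragma: no cover - guarded by NucleationOptions
            raise ConfigError(f"unknown mode {mode!r}")

    @staticmethod
    def _check_anchors(anchors):
        if np.any(anchors[:, 1] < 0) or np.any(anchors[:, 1] > 1):
            raise ConfigError("P_im anchors must lie in [0, 1]")
        if np.any(anchors[:, 0] <= 0) or np.any(anchors[:, 0] >= 1):
            raise ConfigError("f1 anchors must lie in (0, 1)")

    def __call__(self, f1):
        f1_arr = np.asarray(f1, dtype=float)
        if np.any(f1_arr <= 0) or np.any(f1_arr >= 1):
            raise ConfigError("f1 must lie in (0, 1)")
        out = np.clip(self._fn(f1_arr), 0.0, 1.0)
        return float(out) if np.isscalar(f1) or out.ndim == 0 else out


def nucleation_probability(f1: float,
                           provider: NucleationProbabilityProvider) -> float:
    """Immersion-nucleation probability P_im for blend API fraction f1."""
    return provider(f1)


def immersion_nucleus_volumes(v_d: float, phi_cp: float):
    """Immersion nucleus total and solid volume from one drop.

    At the critical-packing liquid fraction phi_cp, a drop of volume v_d
    draws in solids until saturated:
    v_im = v_d (1 + (1 - phi_cp)/phi_cp), v_im_s = v_d (1 - phi_cp)/phi_cp.
    """
    if not 0.0 < phi_cp < 1.0:
        raise ConfigError(f"phi_cp must lie in (0, 1), got {phi_cp}")
    if v_d <= 0:
        raise ConfigError("drop volume must be positive")
    v_im_s = v_d * (1.0 - phi_cp) / phi_cp
    return v_d + v_im_s, v_im_s


def solid_spread_nucleus_volumes(d_d: float, d_p: float):
    """Marble volume and API shell volume: v_ss = (pi/6)(d_d + 2 d_p)^3."""
    if d_d <= 0 or d_p < 0:
        raise ConfigError("require d_d > 0 and d_p >= 0")
    v_ss = float(volume_from_diameter(d_d + 2.0 * d_p))
    v_d = float(volume_from_diameter(d_d))
    return v_ss, v_ss - v_d


@dataclass(frozen=True)
class NucleusSpec:
    """Geometry of the two nucleus types for a given drop and formulation."""

    v_d: float
    v_im: float
    v_im_s: float
    v_ss: float
    v_ss_s1: float
    D_ss: float

    @classmethod
    def from_config(cls, materials: MaterialSet,
                    process: ProcessConditions) -> "NucleusSpec":
        v_d = process.v_d
        v_im, v_im_s = immersion_nucleus_volumes(v_d, materials.phi_cp)
        v_ss, v_ss_s1 = solid_spread_nucleus_volumes(process.d_d, materials.d_p)
        return cls(v_d=v_d, v_im=v_im, v_im_s=v_im_s, v_ss=v_ss,
                   v_ss_s1=v_ss_s1, D_ss=process.d_d + 2.0 * materials.d_p)


def _bed_volume_fractions(bulk: BulkPhase, materials: MaterialSet):
    """Solid-volume fractions of the remaining powder bed."""
    v1 = bulk.Ms1 / materials.rho_s1
    v2 = bulk.Ms2 / materials.rho_s2
    total = v1 + v2
    if total <= 0:
        return 0.0, 0.0
    return v1 / total, v2 / total


def immersion_nucleation_step(ensemble: GranuleEnsemble, bulk: BulkPhase,
                              materials: MaterialSet, spec: NucleusSpec,
                              q_nuc: float, p_im: float, dt: float) -> float:
    """Convert drops hitting the powder bed into immersion nuclei.

    ``q_nuc`` is the volumetric spray rate reaching un-granulated powder.
    Nuclei enter the first occupied region of the grid at the bed's solid
    composition with pore volume v_d, fully saturated (li = p = v_d).
    The powder reservoirs are debited by the solid mass drawn in; the
    nucleus count is capped if the bed cannot supply it.  Returns the
    number of nuclei formed.
    """
    if dt <= 0 or q_nuc <= 0 or p_im <= 0:
        return 0.0
    n_im = p_im * q_nuc * dt / spec.v_d
    fv1, fv2 = _bed_volume_fractions(bulk, materials)
    if fv1 + fv2 <= 0:
        return 0.0
    # cap by available powder mass
    need_m1 = n_im * fv1 * spec.v_im_s * materials.rho_s1
    need_m2 = n_im * fv2 * spec.v_im_s * materials.rho_s2
    scale = 1.0
    if need_m1 > bulk.Ms1 and need_m1 > 0:
        scale = min(scale, bulk.Ms1 / need_m1)
    if need_m2 > bulk.Ms2 and need_m2 > 0:
        scale = min(scale, bulk.Ms2 / need_m2)
    n_im *= scale
    if n_im <= 0:
        return 0.0
    s1 = fv1 * spec.v_im_s
    s2 = fv2 * spec.v_im_s
    redistribute_cell_average(
        ensemble, [[s1, s2, spec.v_d]], [n_im], le_per=0.0, li_per=spec.v_d,
    )
    ensemble.enforce_saturation()
    bulk.Ms1 -= n_im * fv1 * spec.v_im_s * materials.rho_s1
    bulk.Ms2 -= n_im * fv2 * spec.v_im_s * materials.rho_s2
    return n_im


def solid_spread_nucleation_step(ensemble: GranuleEnsemble, bulk: BulkPhase,
                                 materials: MaterialSet, spec: NucleusSpec,
                                 q_nuc: float, p_im: float, dt: float) -> float:
    """Convert the remaining drops into solid-spread (marble) nuclei.

    The marble count grows by (1 - P_im) Q dt / v_d; the API mass drawn
    from the bed is f1 * N_ss * rho_s1 * v_ss_s1 at the current bed mass
    fraction f1, and exactly that solid volume is booked to the class so
    the API balance closes.  Each marble carries its drop as (surface)
    liquid, released to the granule phase when the class converts.
    """
    if dt <= 0 or q_nuc <= 0 or p_im >= 1.0:
        return 0.0
    n_ss = (1.0 - p_im) * q_nuc * dt / spec.v_d
    f1_bed, _ = bulk.bed_mass_fractions()
    need_m1 = f1_bed * n_ss * materials.rho_s1 * spec.v_ss_s1
    if need_m1 > bulk.Ms1 and need_m1 > 0:
        n_ss *= bulk.Ms1 / need_m1
        need_m1 = bulk.Ms1
    if n_ss <= 0:
        return 0.0
    ensemble.Fss += n_ss
    ensemble.ss_api_volume += need_m1 / materials.rho_s1
    ensemble.ss_drop_volume += n_ss * spec.v_d
    bulk.Ms1 -= need_m1
    return n_ss
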