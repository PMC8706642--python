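"""Discretized state space of the three-coordinate population balance.

A granule is described by three internal coordinates — API solid volume
``s1``, excipient solid volume ``s2`` and pore volume ``p`` — discretized
on a shared geometric volume grid, plus lumped external (``le``) and
internal (``li``) liquid volumes carried per grid cell.  Internal liquid
sits inside pores (li <= p per particle); external liquid wets the
surface and drives layering and viscous/capillary aggregation.

Liquid is stored as *cell totals* (``Le``, ``Li``), so every transport
operation conserves binder volume exactly; per-particle averages are
derived on demand by dividing by the cell count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "GranuleEnsemble",
    "BulkPhase",
    "build_grid",
    "granule_volume",
    "surface_area",
    "porosity_and_content",
    "diameter_from_volume",
    "volume_from_diameter",
    "redistribute_cell_average",
    "InvalidStateError",
]


class InvalidStateError(ValueError):
    """A physically inadmissible state or argument was encountered."""


def volume_from_diameter(d):
    """Sphere-equivalent volume v = (pi/6) d^3."""
    return math.pi / 6.0 * np.asarray(d, dtype=float) ** 3


def diameter_from_volume(v):
    """Sphere-equivalent diameter d = (6v/pi)^(1/3)."""
    return np.cbrt(6.0 * np.asarray(v, dtype=float) / math.pi)


def granule_volume(s1, s2, le, p):
    """Total granule volume v = s1 + s2 + le + p.

    Internal liquid occupies pore space and does not add to the envelope
    volume.
    """
    s1, s2, le, p = (np.asarray(x, dtype=float) for x in (s1, s2, le, p))
    if np.any(s1 < 0) or np.any(s2 < 0) or np.any(le < 0) or np.any(p < 0):
        raise InvalidStateError("granule coordinate volumes must be non-negative")
    return s1 + s2 + le + p


def surface_area(v):
    """Sphere-equivalent surface area a = pi^(1/3) (6v)^(2/3)."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise InvalidStateError("volume must be non-negative")
    return np.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0)


def porosity_and_content(s1, s2, le, p):
    """Porosity eps = p/v and API volumetric content q = s1/v."""
    v = granule_volume(s1, s2, le, p)
    if np.any(v <= 0):
        raise InvalidStateError("porosity/content undefined for zero-volume granule")
    return np.asarray(p, dtype=float) / v, np.asarray(s1, dtype=float) / v


@dataclass(frozen=True)
class VolumeGrid:
    """Geometric discretization shared by the three internal coordinates.

    ``volumes[i] = base_volume * ratio**i`` (strictly increasing).
    """

    base_volume: float
    ratio: float
    n_bins: int
    volumes: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.n_bins < 2:
            raise InvalidStateError("n_bins must be at least 2")
        if self.base_volume <= 0 or self.ratio <= 1:
            raise InvalidStateError("require base_volume > 0 and ratio > 1")
        if self.volumes is None:
            vols = self.base_volume * self.ratio ** np.arange(self.n_bins)
            object.__setattr__(self, "volumes", vols)

    @property
    def diameters(self) -> np.ndarray:
        return diameter_from_volume(self.volumes)

    def locate(self, targets):
        """Cell-average bracketing of target volumes on the grid.

        Returns ``(lo, hi, w_lo, clamped_volume)`` where the deposit puts
        fraction ``w_lo`` of the number at bin ``lo`` and ``1 - w_lo`` at
        ``hi`` such that both number and first moment are conserved for
        on-grid targets.  Off-grid targets are clamped to the boundary
        bin and the signed per-particle volume defect (target - assigned)
        is returned for the conservation ledger.
        """
        t = np.asarray(targets, dtype=float)
        v = self.volumes
        hi = np.searchsorted(v, t)
        lo = np.clip(hi - 1, 0, self.n_bins - 1)
        hi = np.clip(hi, 0, self.n_bins - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            w_lo = np.where(hi > lo, (v[hi] - t) / (v[hi] - v[lo]), 1.0)
        below = t <= v[0]
        above = t >= v[-1]
        w_lo = np.where(below, 1.0, w_lo)
        w_lo = np.where(above, 0.0, w_lo)
        lo = np.where(above, self.n_bins - 1, lo)
        hi = np.where(below, 0, hi)
        w_lo = np.clip(w_lo, 0.0, 1.0)
        defect = np.where(below, t - v[0], np.where(above, t - v[-1], 0.0))
        return lo, hi, w_lo, defect


def build_grid(base_diameter: float, max_diameter: float, n_bins: int,
               ratio_mode: str = "fit_span") -> VolumeGrid:
    """Build the geometric volume grid from a diameter span.

    ``fit_span`` chooses the ratio so that bin ``n_bins`` lands exactly on
    ``max_diameter``; ``fixed_ratio_4`` uses the fixed volume ratio 4 from
    the base volume (the span is then ignored beyond the base).
    """
    if base_diameter <= 0 or max_diameter <= 0:
        raise InvalidStateError("diameters must be positive")
    if base_diameter >= max_diameter:
        raise InvalidStateError("base_diameter must be smaller than max_diameter")
    if n_bins < 2:
        raise InvalidStateError("n_bins must be at least 2")
    v_min = float(volume_from_diameter(base_diameter))
    v_max = float(volume_from_diameter(max_diameter))
    if ratio_mode == "fixed_ratio_4":
        ratio = 4.0
    elif ratio_mode == "fit_span":
        ratio = (v_max / v_min) ** (1.0 / (n_bins - 1))
    else:
        raise InvalidStateError(f"unknown ratio_mode {ratio_mode!r}")
    return VolumeGrid(base_volume=v_min, ratio=ratio, n_bins=n_bins)


@dataclass
class BulkPhase:
    """Un-granulated powder reservoirs and binder accounting (kg, m3)."""

    Ms1: float
    Ms2: float
    liquid_sprayed: float = 0.0
    liquid_remaining: float = 0.0

    @property
    def mass(self) -> float:
        return self.Ms1 + self.Ms2

    def bed_mass_fractions(self):
        """(f1, f2) mass fractions of the remaining powder bed."""
        total = self.Ms1 + self.Ms2
        if total <= 0:
            return 0.0, 0.0
        return self.Ms1 / total, self.Ms2 / total


@dataclass
class GranuleEnsemble:
    """Number density ``F`` over the (s1, s2, p) grid plus liquid totals.

    ``Fss`` is the lumped solid-spread ("liquid marble") nuclei class:
    ``ss_api_volume`` is the total API solid volume booked to the class
    and ``ss_drop_volume`` the total binder volume carried by the marbles.
    ``ledger`` accumulates signed boundary-clamp volume defects per
    coordinate for the conservation audit.
    """

    grid: VolumeGrid
    F: np.ndarray = None
    Le: np.ndarray = None
    Li: np.ndarray = None
    Fss: float = 0.0
    ss_api_volume: float = 0.0
    ss_drop_volume: float = 0.0
    ledger: dict = field(default_factory=lambda: {"s1": 0.0, "s2": 0.0, "p": 0.0})

    def __post_init__(self):
        n = self.grid.n_bins
        shape = (n, n, n)
        if self.F is None:
            self.F = np.zeros(shape)
        if self.Le is None:
            self.Le = np.zeros(shape)
        if self.Li is None:
            self.Li = np.zeros(shape)

    # --- representative coordinates -----------------------------------
    @property
    def s1_axis(self) -> np.ndarray:
        return self.grid.volumes[:, None, None]

    @property
    def s2_axis(self) -> np.ndarray:
        return self.grid.volumes[None, :, None]

    @property
    def p_axis(self) -> np.ndarray:
        return self.grid.volumes[None, None, :]

    # --- moments -------------------------------------------------------
    def total_number(self) -> float:
        return float(self.F.sum())

    def total_s1(self) -> float:
        return float((self.F * self.s1_axis).sum())

    def total_s2(self) -> float:
        return float((self.F * self.s2_axis).sum())

    def total_pore(self) -> float:
        return float((self.F * self.p_axis).sum())

    def total_liquid(self) -> float:
        return float(self.Le.sum() + self.Li.sum())

    def occupied(self, rel_threshold: float = 0.0):
        """Indices (3, m) of cells with F above rel_threshold * total."""
        cut = rel_threshold * self.total_number()
        return np.nonzero(self.F > cut)

    def copy(self) -> "GranuleEnsemble":
        return GranuleEnsemble(
            grid=self.grid, F=self.F.copy(), Le=self.Le.copy(), Li=self.Li.copy(),
            Fss=self.Fss, ss_api_volume=self.ss_api_volume,
            ss_drop_volume=self.ss_drop_volume, ledger=dict(self.ledger),
        )

    # --- per-cell granule properties ----------------------------------
    def cell_properties(self, idx):
        """Per-particle property arrays for the cells indexed by ``idx``.

        Returns a dict with s1, s2, p, le, li, v, a, d for the selected
        cells (per-particle averages for the liquids).
        """
        F = self.F[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            le = np.where(F > 0, self.Le[idx] / F, 0.0)
            li = np.where(F > 0, self.Li[idx] / F, 0.0)
        s1 = self.grid.volumes[idx[0]]
        s2 = self.grid.volumes[idx[1]]
        p = self.grid.volumes[idx[2]]
        v = s1 + s2 + le + p
        return {
            "F": F, "s1": s1, "s2": s2, "p": p, "le": le, "li": li,
            "v": v, "a": surface_area(v), "d": diameter_from_volume(v),
        }

    def enforce_saturation(self):
        """Move internal liquid exceeding pore capacity to the surface.

        After a redistribution, a fraction of a cell's population may land
        in a pore bin smaller than its internal liquid load; the excess is
        squeezed out to external liquid (total binder conserved).
        """
        cap = self.F * self.p_axis
        excess = np.maximum(self.Li - cap, 0.0)
        if excess.any():
            self.Li -= excess
            self.Le += excess

    def to_frame(self) -> pd.DataFrame:
        """Occupied-cell snapshot in long format."""
        idx = np.nonzero(self.F > 0)
        return pd.DataFrame({
            "i": idx[0], "j": idx[1], "k": idx[2],
            "s1": self.grid.volumes[idx[0]],
            "s2": self.grid.volumes[idx[1]],
            "p": self.grid.volumes[idx[2]],
            "F": self.F[idx], "Le": self.Le[idx], "Li": self.Li[idx],
        })

    def save(self, path):
        """Binary restart container (grid + dense state)."""
        np.savez(
            path, volumes=self.grid.volumes, base_volume=self.grid.base_volume,
            ratio=self.grid.ratio, F=self.F, Le=self.Le, Li=self.Li,
            Fss=self.Fss, ss_api_volume=self.ss_api_volume,
            ss_drop_volume=self.ss_drop_volume,
            ledger=np.array([self.ledger["s1"], self.ledger["s2"], self.ledger["p"]]),
        )

    @classmethod
    def load(cls, path) -> "GranuleEnsemble":
        data = np.load(path)
        grid = VolumeGrid(base_volume=float(data["base_volume"]),
                          ratio=float(data["ratio"]), n_bins=len(data["volumes"]))
        led = data["ledger"]
        return cls(grid=grid, F=data["F"], Le=data["Le"], Li=data["Li"],
                   Fss=float(data["Fss"]), ss_api_volume=float(data["ss_api_volume"]),
                   ss_drop_volume=float(data["ss_drop_volume"]),
                   ledger={"s1": float(led[0]), "s2": float(led[1]), "p": float(led[2])})


def redistribute_cell_average(ensemble: GranuleEnsemble, targets, amounts,
                              le_per=0.0, li_per=0.0) -> None:
    """Deposit granules at off-grid coordinates onto the grid, in place.

    ``targets`` is (m, 3) of (s1, s2, p) volumes, ``amounts`` (m,) the
    number of granules, ``le_per``/``li_per`` per-granule liquid volumes.
    Each coordinate is split between its bracketing bins so that number
    and the coordinate's first moment are conserved (tensor-product cell
    average); attached liquid follows the number fractions.  Targets
    outside the grid span are clamped to the boundary bin and the volume
    defect is recorded in ``ensemble.ledger``.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    amounts = np.atleast_1d(np.asarray(amounts, dtype=float))
    if np.any(amounts < 0):
        raise InvalidStateError("deposit amounts must be non-negative")
    le_per = np.broadcast_to(np.asarray(le_per, dtype=float), amounts.shape)
    li_per = np.broadcast_to(np.asarray(li_per, dtype=float), amounts.shape)
    keep = amounts > 0
    if not keep.any():
        return
    targets, amounts = targets[keep], amounts[keep]
    le_per, li_per = le_per[keep], li_per[keep]

    names = ("s1", "s2", "p")
    los, his, ws = [], [], []
    for c in range(3):
        lo, hi, w_lo, defect = ensemble.grid.locate(targets[:, c])
        ensemble.ledger[names[c]] += float((defect * amounts).sum())
        los.append(lo)
        his.append(hi)
        ws.append(w_lo)

    m = len(amounts)
    for corner in range(8):
        bits = ((corner >> 0) & 1, (corner >> 1) & 1, (corner >> 2) & 1)
        w = np.ones(m)
        ii = []
        for c, bit in enumerate(bits):
            w = w * (ws[c] if bit == 0 else (1.0 - ws[c]))
            ii.append(los[c] if bit == 0 else his[c])
        mask = w > 0
        if not mask.any():
            continue
        dep = amounts[mask] * w[mask]
        sel = (ii[0][mask], ii[1][mask], ii[2][mask])
        np.add.at(ensemble.F, sel, dep)
        np.add.at(ensemble.Le, sel, dep * le_per[mask])
        np.add.at(ensemble.Li, sel, dep * li_per[mask])


def move_cells(ensemble: GranuleEnsemble, idx, new_targets) -> None:
    """Relocate whole cell populations to new coordinates, in place.

    Used by the continuous rate processes (layering, surface growth,
    consolidation): the population of each cell in ``idx`` is removed and
    re-deposited at ``new_targets`` (m, 3) with its liquid totals carried
    along, then pore saturation is re-enforced.
    """
    F = ensemble.F[idx].copy()
    Le = ensemble.Le[idx].copy()
    Li = ensemble.Li[idx].copy()
    keep = F > 0
    if not keep.any():
        return
    ensemble.F[idx] = 0.0
    ensemble.Le[idx] = 0.0
    ensemble.Li[idx] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        le_per = np.where(keep, Le / np.where(keep, F, 1.0), 0.0)
        li_per = np.where(keep, Li / np.where(keep, F, 1.0), 0.0)
    redistribute_cell_average(
        ensemble, np.atleast_2d(new_targets)[keep], F[keep],
        le_per=le_per[keep], li_per=li_per[keep],
    )
    ensemble.enforce_saturation()
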