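"""Post-processing: size statistics, content uniformity, sensitivity.

The demixing potential DP% quantifies how unevenly the API is spread
across granule size classes: DP% = (100 / x_bar) sqrt(sum w (x - x_bar)^2)
with x the per-class API mass fraction, w the class weight fraction and
x_bar the weighted mean — a relative standard deviation across classes,
zero iff every class carries the blend composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_state import GranuleEnsemble, InvalidStateError

__all__ = [
    "SizeStatistics",
    "size_statistics",
    "size_class_table",
    "demixing_potential",
    "ensemble_averages",
    "sensitivity_scan",
    "SENSITIVITY_PARAMETERS",
]


@dataclass
class SizeStatistics:
    """Volume-weighted cumulative size distribution and its quantiles."""

    diameters: np.ndarray
    cumulative: np.ndarray
    d10: float
    d50: float
    d90: float

    def quantile(self, frac: float) -> float:
        return float(np.interp(frac, self.cumulative, self.diameters))


def _collapse_by_diameter(ensemble: GranuleEnsemble):
    """Occupied cells collapsed onto sphere-equivalent diameter."""
    idx = ensemble.occupied()
    if len(idx[0]) == 0:
        raise InvalidStateError("size statistics undefined for an empty ensemble")
    props = ensemble.cell_properties(idx)
    order = np.argsort(props["d"])
    return {k: v[order] for k, v in props.items()}


def size_statistics(ensemble: GranuleEnsemble) -> SizeStatistics:
    """Volume-weighted cumulative distribution over granule diameter.

    Quantiles (d10/d50/d90) come from monotone linear interpolation of
    the cumulative curve at the cell diameters.
    """
    props = _collapse_by_diameter(ensemble)
    weight = props["F"] * props["v"]
    cum = np.cumsum(weight)
    cum /= cum[-1]
    return SizeStatistics(
        diameters=props["d"], cumulative=cum,
        d10=float(np.interp(0.10, cum, props["d"])),
        d50=float(np.interp(0.50, cum, props["d"])),
        d90=float(np.interp(0.90, cum, props["d"])),
    )


def size_class_table(ensemble: GranuleEnsemble, rho_s1: float, rho_s2: float,
                     edges=None) -> pd.DataFrame:
    """Per-size-class weight fraction and API content for uniformity work.

    Classes default to the simulation grid's diameter decades (one class
    per total-volume bin, collapsed over composition and porosity).
    ``w`` is the granule solid-mass fraction of the class and ``x`` the
    API mass fraction of the solids in it.
    """
    props = _collapse_by_diameter(ensemble)
    if edges is None:
        gd = ensemble.grid.diameters
        edges = np.concatenate([[0.0], np.sqrt(gd[:-1] * gd[1:]), [np.inf]])
    edges = np.asarray(edges, dtype=float)
    cls = np.clip(np.searchsorted(edges, props["d"], side="right") - 1,
                  0, len(edges) - 2)
    m_api = rho_s1 * props["F"] * props["s1"]
    m_exc = rho_s2 * props["F"] * props["s2"]
    rows = []
    for c in np.unique(cls):
        in_c = cls == c
        api = m_api[in_c].sum()
        solids = api + m_exc[in_c].sum()
        if solids <= 0:
            continue
        rows.append({
            "d_lo": edges[c], "d_hi": edges[c + 1],
            "w": solids, "x": api / solids,
        })
    table = pd.DataFrame(rows)
    table["w"] /= table["w"].sum()
    return table


def demixing_potential(table: pd.DataFrame) -> float:
    """DP% across size classes; requires columns ``w`` and ``x``."""
    w = np.asarray(table["w"], dtype=float)
    x = np.asarray(table["x"], dtype=float)
    if abs(w.sum() - 1.0) > 1e-8:
        raise InvalidStateError("class weights must sum to 1")
    if np.any(w < 0) or np.any(x < 0) or np.any(x > 1):
        raise InvalidStateError("invalid class weights or contents")
    x_bar = float((w * x).sum())
    if x_bar <= 0:
        raise InvalidStateError("demixing potential undefined without API")
    return 100.0 / x_bar * float(np.sqrt((w * (x - x_bar) ** 2).sum()))


def ensemble_averages(ensemble: GranuleEnsemble, f1_volume: float) -> dict:
    """Number- and volume-weighted granule-average properties.

    Returns porosity, liquid fraction (le + li)/v and API volumetric
    content q under both weightings, plus dq: the gap between the blend
    API solid-volume fraction and the volume-weighted average q.
    """
    props = _collapse_by_diameter(ensemble)
    eps = props["p"] / props["v"]
    liq = (props["le"] + props["li"]) / props["v"]
    q = props["s1"] / props["v"]
    n_w = props["F"] / props["F"].sum()
    v_w = props["F"] * props["v"]
    v_w = v_w / v_w.sum()
    out = {}
    for name, val in (("porosity", eps), ("liquid_fraction", liq), ("q", q)):
        out[f"{name}_number"] = float((n_w * val).sum())
        out[f"{name}_volume"] = float((v_w * val).sum())
    out["dq"] = f1_volume - out["q_volume"]
    return out


SENSITIVITY_PARAMETERS = {
    "beta0": ("rates", "beta0"),
    "e_s1": ("materials", "e_s1"),
    "e_s2": ("materials", "e_s2"),
    "k_con": ("rates", "k_con"),
    "k_layer": ("rates", "k_layer"),
    "k_sg": ("rates", "k_sg"),
}

_DEFAULT_OUTPUTS = ("d10", "d50", "d90", "porosity_volume", "q_volume")


def sensitivity_scan(config, parameters=None,
                     perturbations=(-0.2, -0.1, 0.1, 0.2),
                     outputs=_DEFAULT_OUTPUTS) -> pd.DataFrame:
    """Relative one-at-a-time sensitivity of end-of-run outputs.

    Each tuned parameter is multiplied by (1 + delta) and the run is
    repeated; sensitivity = (Y0 - Y_i) / Y0 per output.  A zero
    perturbation row is identically zero by construction.  Failed runs
    leave NaN rows and the scan continues.
    """
    from .simulate import run_simulation

    if parameters is None:
        parameters = list(SENSITIVITY_PARAMETERS)
    base = run_simulation(config)
    y0 = {k: base.summary()[k] for k in outputs}
    rows = []
    for name in parameters:
        group, attr = SENSITIVITY_PARAMETERS[name]
        base_value = getattr(getattr(config, group), attr)
        for delta in perturbations:
            row = {"parameter": name, "perturbation": delta}
            if delta == 0:
                row.update({k: 0.0 for k in outputs})
                rows.append(row)
                continue
            try:
                cfg = config.replace(**{group: {attr: base_value * (1.0 + delta)}})
                rec = run_simulation(cfg)
                summ = rec.summary()
                row.update({k: (y0[k] - summ[k]) / y0[k] for k in outputs})
            except Exception:
                row.update({k: np.nan for k in outputs})
            rows.append(row)
    return pd.DataFrame(rows)
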