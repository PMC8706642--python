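"""Shear-driven binary breakage (default off).

A granule breaks at rate K = p_brk * gamma * d^n into two daughters that
split every internal coordinate — and the attached liquid — in fixed
proportions (theta, 1 - theta), so all first moments are conserved by
construction and number can only increase.  The published model keeps
its breakage sub-model in an appendix that is not reproduced here; this
configurable shear-proportional form stands in for it and ships disabled
(p_brk = 0) so the growth-dominated headline behaviour is unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import BreakageOptions
from .grid_state import GranuleEnsemble, redistribute_cell_average

__all__ = ["BreakageRates", "breakage_rates", "breakage_step"]


@dataclass
class BreakageRates:
    """Per-cell parent depletion rate (1/s per granule) for CFL control."""

    rate: np.ndarray

    def max_outflow_fraction_time(self, ensemble: GranuleEnsemble) -> float:
        mask = self.rate > 0
        if not mask.any():
            return np.inf
        return 1.0 / float(self.rate[mask].max())


def breakage_rates(ensemble: GranuleEnsemble, options: BreakageOptions,
                   gamma: float) -> BreakageRates:
    """Specific breakage rate K(d) on occupied cells."""
    rate = np.zeros_like(ensemble.F)
    if not options.enabled or options.p_brk <= 0:
        return BreakageRates(rate=rate)
    idx = ensemble.occupied()
    if len(idx[0]) == 0:
        return BreakageRates(rate=rate)
    props = ensemble.cell_properties(idx)
    rate[idx] = options.p_brk * gamma * props["d"] ** options.size_exponent
    return BreakageRates(rate=rate)


def breakage_step(ensemble: GranuleEnsemble, options: BreakageOptions,
                  gamma: float, dt: float) -> None:
    """Apply one Euler breakage step in place.

    Each event removes one parent and deposits two daughters carrying
    fractions theta and 1 - theta of every coordinate and of the
    parent's liquid.
    """
    if not options.enabled or options.p_brk <= 0 or dt <= 0:
        return
    rates = breakage_rates(ensemble, options, gamma)
    idx = np.nonzero(rates.rate > 0)
    if len(idx[0]) == 0:
        return
    props = ensemble.cell_properties(idx)
    events = np.minimum(rates.rate[idx] * dt, 1.0) * props["F"]
    live = events > 0
    if not live.any():
        return
    events = events[live]
    sel = tuple(ax[live] for ax in idx)
    frac_removed = events / props["F"][live]
    # remove parents with their share of the cell liquid
    ensemble.F[sel] -= events
    ensemble.Le[sel] *= (1.0 - frac_removed)
    ensemble.Li[sel] *= (1.0 - frac_removed)
    for theta in (options.daughter_theta, 1.0 - options.daughter_theta):
        targets = np.column_stack([
            theta * props["s1"][live],
            theta * props["s2"][live],
            theta * props["p"][live],
        ])
        redistribute_cell_average(
            ensemble, targets, events,
            le_per=theta * props["le"][live], li_per=theta * props["li"][live],
        )
    ensemble.enforce_saturation()
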