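"""Synthetic experiments and two-objective Pareto parameter estimation.

Real calibration data for this process are cumulative granule size
distributions and per-size-class API content tables.  ``make_fixture``
manufactures such tables by running the forward model at known "true"
parameters and optionally corrupting the observations with multiplicative
Gaussian noise, enabling closed-loop parameter-recovery studies with no
external data.

``pareto_fit`` estimates the six tuned parameters (beta0, e_s1, e_s2,
k_con, k_layer, k_sg) by weighted-sum scalarization of the two error
objectives (size SSE, content SSE), one bounded derivative-free
optimization per weight, returning the mutually non-dominated set and a
knee-point compromise.  Orders-of-magnitude parameters are searched in
log10 space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .analysis import SENSITIVITY_PARAMETERS, size_class_table, size_statistics
from .config import SimulationConfig
from .grid_state import InvalidStateError
from .simulate import run_simulation

__all__ = [
    "ExperimentFixture",
    "CalibrationResult",
    "make_fixture",
    "objectives",
    "pareto_fit",
    "apply_parameters",
    "PARAMETER_NAMES",
]

PARAMETER_NAMES = ("beta0", "e_s1", "e_s2", "k_con", "k_layer", "k_sg")
_LOG_PARAMS = frozenset({"beta0", "k_con", "k_layer", "k_sg"})


def apply_parameters(config: SimulationConfig, params: dict) -> SimulationConfig:
    """Return a config with the tuned parameters overridden."""
    groups: dict = {}
    for name, value in params.items():
        group, attr = SENSITIVITY_PARAMETERS[name]
        groups.setdefault(group, {})[attr] = float(value)
    return config.replace(**groups)


@dataclass
class ExperimentFixture:
    """A synthetic 'measured' dataset for one formulation run."""

    diameters: np.ndarray        # CSD observation diameters, m
    cumulative: np.ndarray       # cumulative volume fraction at diameters
    content_edges: np.ndarray    # size-class edges for the content table, m
    content_x: np.ndarray        # API mass fraction per class (NaN = unobserved)
    f1: float
    ls_ratio: float
    noise_sd: float
    seed: int
    true_params: dict = field(default_factory=dict)

    def to_frames(self):
        csd = pd.DataFrame({"diameter": self.diameters,
                            "cumulative_volume_fraction": self.cumulative})
        content = pd.DataFrame({"d_lo": self.content_edges[:-1],
                                "d_hi": self.content_edges[1:],
                                "x_api": self.content_x})
        return csd, content


def _default_observation_grid(config: SimulationConfig):
    d = np.geomspace(50e-6, 0.5 * config.numerics.d_max, 12)
    edges = np.geomspace(config.numerics.d_min, config.numerics.d_max, 7)
    edges[0], edges[-1] = 0.0, np.inf
    return d, edges


def _observe(config: SimulationConfig, diameters, edges):
    record = run_simulation(config)
    ens = record.final_ensemble
    if ens.total_number() <= 0:
        raise InvalidStateError("forward model produced no granules")
    stats = size_statistics(ens)
    cum = np.interp(diameters, stats.diameters, stats.cumulative,
                    left=0.0, right=1.0)
    table = size_class_table(ens, config.materials.rho_s1,
                             config.materials.rho_s2, edges=edges)
    x = np.full(len(edges) - 1, np.nan)
    lo = np.asarray(table["d_lo"])
    for row_lo, row_x in zip(lo, table["x"]):
        k = int(np.searchsorted(edges, row_lo, side="right") - 1)
        x[k] = row_x
    return cum, x


def make_fixture(config: SimulationConfig, true_params: dict,
                 noise_sd: float = 0.0, seed: int = 0,
                 diameters=None) -> ExperimentFixture:
    """Run the forward model at known parameters and 'measure' it.

    Multiplicative Gaussian noise of relative standard deviation
    ``noise_sd`` is applied to every observation; the cumulative curve
    is then re-monotonized and clipped to [0, 1].  Deterministic in
    ``seed``.
    """
    cfg = apply_parameters(config, true_params).validate()
    default_d, edges = _default_observation_grid(cfg)
    diameters = np.asarray(diameters, dtype=float) if diameters is not None else default_d
    cum, x = _observe(cfg, diameters, edges)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cum = cum * (1.0 + noise_sd * rng.standard_normal(cum.shape))
        cum = np.clip(np.maximum.accumulate(cum), 0.0, 1.0)
        x = x * (1.0 + noise_sd * rng.standard_normal(x.shape))
        x = np.clip(x, 0.0, 1.0)
    return ExperimentFixture(
        diameters=diameters, cumulative=cum, content_edges=edges, content_x=x,
        f1=cfg.materials.f1, ls_ratio=cfg.process.ls_ratio,
        noise_sd=noise_sd, seed=seed, true_params=dict(true_params),
    )


def objectives(candidate_params: dict, fixture: ExperimentFixture,
               base_config: SimulationConfig):
    """(SSE_size, SSE_content) of a candidate against one fixture.

    The candidate is simulated under the fixture's formulation; failures
    return an infinite sentinel so the optimizer steps away.
    """
    cfg = apply_parameters(base_config, candidate_params)
    cfg = cfg.replace(materials={"f1": fixture.f1},
                      process={"ls_ratio": fixture.ls_ratio})
    try:
        cum, x = _observe(cfg, fixture.diameters, fixture.content_edges)
    except Exception:
        return math.inf, math.inf
    sse_size = float(np.sum((cum - fixture.cumulative) ** 2))
    seen = ~np.isnan(fixture.content_x) & ~np.isnan(x)
    sse_content = float(np.sum((x[seen] - fixture.content_x[seen]) ** 2))
    return sse_size, sse_content


@dataclass
class CalibrationResult:
    """Non-dominated parameter vectors with objectives and a compromise."""

    members: list                # list of parameter dicts
    objective_values: np.ndarray  # (m, 2) array of (SSE_size, SSE_content)
    compromise: dict             # knee-point member
    history: pd.DataFrame = None

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.members)
        df["sse_size"] = self.objective_values[:, 0]
        df["sse_content"] = self.objective_values[:, 1]
        return df


def default_bounds(config: SimulationConfig) -> dict:
    """Search bounds: one decade around defaults; restitutions in [0.01, 0.6]."""
    out = {}
    for name in PARAMETER_NAMES:
        group, attr = SENSITIVITY_PARAMETERS[name]
        val = getattr(getattr(config, group), attr)
        if name in _LOG_PARAMS:
            out[name] = (val / 10.0, val * 10.0)
        else:
            out[name] = (0.01, 0.6)
    return out


def _to_unit(values, bounds):
    z = []
    for v, (lo, hi), name in zip(values, bounds.values(), bounds.keys()):
        if name in _LOG_PARAMS:
            z.append((math.log10(v) - math.log10(lo))
                     / (math.log10(hi) - math.log10(lo)))
        else:
            z.append((v - lo) / (hi - lo))
    return np.array(z)


def _from_unit(z, bounds):
    out = {}
    for zi, (name, (lo, hi)) in zip(z, bounds.items()):
        zi = min(max(float(zi), 0.0), 1.0)
        if name in _LOG_PARAMS:
            out[name] = 10 ** (math.log10(lo) + zi * (math.log10(hi) - math.log10(lo)))
        else:
            out[name] = lo + zi * (hi - lo)
    return out


def _non_dominated(values: np.ndarray) -> np.ndarray:
    keep = np.ones(len(values), dtype=bool)
    for i in range(len(values)):
        if not keep[i]:
            continue
        dominated = np.all(values <= values[i], axis=1) & np.any(
            values < values[i], axis=1)
        if dominated.any():
            keep[i] = False
    return keep


def pareto_fit(fixtures, base_config: SimulationConfig, bounds: dict = None,
               n_weights: int = 3, seed: int = 0, n_presample: int = 16,
               maxfev: int = 150) -> CalibrationResult:
    """Weighted-sum Pareto estimation of the six tuned parameters.

    For each weight w in [0, 1] the scalar objective
    w * SSE_size + (1 - w) * SSE_content (summed over fixtures) is
    minimized by a seeded Latin-hypercube presample followed by bounded
    Powell refinement in the unit-cube parameterization.  Results are
    pruned to the non-dominated set; the compromise member minimizes the
    normalized distance to the ideal point.  Deterministic in ``seed``.
    """
    if not fixtures:
        raise InvalidStateError("at least one fixture is required")
    bounds = bounds or default_bounds(base_config)
    cache: dict = {}

    def evaluate(z):
        key = tuple(np.round(np.asarray(z, dtype=float), 6))
        if key not in cache:
            params = _from_unit(key, bounds)
            pair = np.array([0.0, 0.0])
            for fx in fixtures:
                pair += np.array(objectives(params, fx, base_config))
            cache[key] = pair
        return cache[key]

    dim = len(bounds)
    weights = (np.linspace(0.0, 1.0, n_weights) if n_weights > 1
               else np.array([0.5]))
    solutions = []
    for iw, w in enumerate(weights):
        def scalar(z):
            s, c = evaluate(z)
            val = w * s + (1.0 - w) * c
            return val if np.isfinite(val) else 1e12

        sampler = qmc.LatinHypercube(d=dim, seed=seed + iw)
        pool = np.vstack([sampler.random(n_presample), np.full((1, dim), 0.5)])
        best = min(pool, key=scalar)
        res = minimize(scalar, best, method="Powell",
                       bounds=[(0.0, 1.0)] * dim,
                       options={"maxfev": maxfev, "xtol": 1e-3, "ftol": 1e-9})
        z = np.clip(res.x, 0.0, 1.0)
        solutions.append((_from_unit(z, bounds), evaluate(z)))

    values = np.array([obj for _, obj in solutions])
    keep = _non_dominated(values)
    members = [p for (p, _), k in zip(solutions, keep) if k]
    kept_vals = values[keep]
    spread = np.ptp(kept_vals, axis=0)
    span = np.where(spread > 0, spread, 1.0)
    norm = (kept_vals - kept_vals.min(axis=0)) / span
    knee = int(np.argmin(np.linalg.norm(norm, axis=1)))
    history = pd.DataFrame(
        [{**_from_unit(np.array(k), bounds), "sse_size": v[0], "sse_content": v[1]}
         for k, v in cache.items()])
    return CalibrationResult(members=members, objective_values=kept_vals,
                             compromise=members[knee], history=history)
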