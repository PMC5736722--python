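"""Stochastic integration of the model systems and the two sampling regimes.

Noise enters as additive white noise in the SDE sense (Euler-Maruyama with
diffusion amplitude ``eta``); with ``eta = 0`` the deterministic sub-steps use
Heun's second-order method instead. ``distributed`` sampling integrates S
independent segments of m samples each from i.i.d. initial conditions
(M = S x m total samples); ``continuous`` sampling records one long segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import dynamics
from .netgen import NetworkSpec

__all__ = [
    "SimConfig",
    "TimeSeriesSet",
    "IntegrationError",
    "simulate",
    "sample",
    "simulate_mm",
    "simulate_phase",
    "simulate_roessler",
    "simulate_glycolysis",
    "simulate_circadian",
    "DEFAULT_DT",
]

# per-model default sampling intervals, chosen so the two-point derivative
# error stays well below the signal (time units of the respective model)
DEFAULT_DT = {
    "mm": 0.25,
    "phase_net": 0.05,
    "phase_hyper": 0.05,
    "roessler": 0.05,
    "glycolysis": 0.01,
    "circadian": 0.25,
}


class IntegrationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    """Simulation settings shared by all model systems.

    ``dt`` is the sampling interval; the internal integrator step is
    ``dt / substeps``. ``m`` samples per segment, ``S`` segments. ``eta`` is
    the standard deviation (diffusion amplitude) of the additive white noise.
    ``omega`` fixes the natural frequencies of the phase models (default:
    drawn i.i.d. standard normal from the seed). ``init`` may be a callable
    ``(rng, S) -> (S, D) array`` overriding the per-model default initial
    conditions. ``wrap`` records phases modulo 2*pi instead of unwrapped.
    """

    dt: float = 0.05
    m: int = 10
    S: int = 100
    eta: float = 0.0
    substeps: int = 10
    seed: int = 0
    params: dict | None = None
    omega: np.ndarray | None = None
    init: object = None
    wrap: bool = False

    def __post_init__(self):
        if self.dt <= 0 or self.substeps < 1:
            raise ValueError("dt must be positive and substeps >= 1")
        if self.m < 1 or self.S < 1:
            raise ValueError("m and S must be >= 1")

    @property
    def M(self) -> int:
        return self.m * self.S


@dataclass
class TimeSeriesSet:
    """Segmented multivariate recordings with a common sampling interval.

    ``segments`` is an ordered list of (m_s, D_total) state arrays sampled at
    t_0 + m*dt; ``unit_layout`` maps unit i to its component column indices
    (one column per unit except three for the chaotic oscillators).
    """

    segments: list
    dt: float
    unit_layout: list
    meta: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return len(self.unit_layout)

    @property
    def n_components(self) -> int:
        return self.segments[0].shape[1]

    @property
    def M(self) -> int:
        return int(sum(s.shape[0] for s in self.segments))

    def stacked(self):
        """All segments stacked: (M, D) state array and (M,) segment ids."""
        X = np.concatenate(self.segments, axis=0)
        seg = np.concatenate(
            [np.full(s.shape[0], k) for k, s in enumerate(self.segments)]
        )
        return X, seg

    def component_names(self) -> list[str]:
        names = [""] * self.n_components
        for i, cols in enumerate(self.unit_layout):
            for d, c in enumerate(cols):
                names[c] = f"u{i + 1}_c{d + 1}"
        return names

    def subset_units(self, units) -> "TimeSeriesSet":
        """Restrict to a subset of (observed) units; used for hidden-unit runs."""
        units = sorted(int(u) for u in units)
        cols = [c for u in units for c in self.unit_layout[u]]
        layout, pos = [], 0
        for u in units:
            k = len(self.unit_layout[u])
            layout.append(list(range(pos, pos + k)))
            pos += k
        meta = dict(self.meta, observed_units=units)
        return TimeSeriesSet(
            segments=[s[:, cols] for s in self.segments],
            dt=self.dt,
            unit_layout=layout,
            meta=meta,
        )


def _noise_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(10_001,)))


def _init_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(10_002,)))


def _omega_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(10_003,)))


def _integrate(f, x0: np.ndarray, cfg: SimConfig, clip_nonneg: bool = False,
               guard: float = 1e6) -> np.ndarray:
    """Advance all segments in one batch; returns (S, m, D) samples."""
    h = cfg.dt / cfg.substeps
    rng = _noise_rng(cfg.seed)
    S, D = x0.shape
    out = np.empty((S, cfg.m, D))
    out[:, 0] = x0
    x = x0.copy()
    sq = math.sqrt(h) * cfg.eta
    for step in range(1, cfg.m):
        for _ in range(cfg.substeps):
            if cfg.eta == 0.0:
                k1 = f(x)
                k2 = f(x + h * k1)
                x = x + 0.5 * h * (k1 + k2)
            else:
                x = x + h * f(x) + sq * rng.standard_normal(x.shape)
            if clip_nonneg:
                np.maximum(x, 0.0, out=x)
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > guard:
            raise IntegrationError(
                f"state diverged (|x| > {guard:g}) at sample {step}; "
                "reduce dt or check parameters"
            )
        out[:, step] = x
    return out


def _default_init(model: str, spec: NetworkSpec | None, rng, S: int) -> np.ndarray:
    if model == "mm":
        return rng.uniform(0.25, 2.0, size=(S, spec.N))
    if model in ("phase_net", "phase_hyper"):
        return rng.uniform(-np.pi, np.pi, size=(S, spec.N))
    if model == "roessler":
        x = np.empty((S, spec.N, 3))
        x[..., 0] = rng.uniform(-10.0, 10.0, size=(S, spec.N))
        x[..., 1] = rng.uniform(-10.0, 10.0, size=(S, spec.N))
        x[..., 2] = rng.uniform(0.0, 1.0, size=(S, spec.N))
        return x.reshape(S, 3 * spec.N)
    if model == "glycolysis":
        lo = np.array([0.2, 1.0, 0.1, 0.1, 0.05, 0.5, 0.05])
        hi = np.array([2.0, 4.0, 0.5, 0.4, 0.6, 3.0, 0.3])
        return rng.uniform(lo, hi, size=(S, 7))
    if model == "circadian":
        return rng.uniform(0.1, 2.0, size=(S, 10))
    raise ValueError(f"unknown model {model!r}")


def simulate(model: str, spec: NetworkSpec | None, cfg: SimConfig) -> TimeSeriesSet:
    """Simulate a named model system under the given configuration."""
    omega = None
    if model in ("phase_net", "phase_hyper"):
        if cfg.omega is not None:
            omega = np.asarray(cfg.omega, dtype=float)
        else:
            omega = _omega_rng(cfg.seed).standard_normal(spec.N)
    f = dynamics.make_rhs(model, spec=spec, params=cfg.params, omega=omega)

    rng = _init_rng(cfg.seed)
    if cfg.init is not None:
        x0 = np.asarray(cfg.init(rng, cfg.S), dtype=float)
    else:
        x0 = _default_init(model, spec, rng, cfg.S)

    nonneg = model in ("mm", "glycolysis", "circadian")
    traj = _integrate(f, x0, cfg, clip_nonneg=nonneg and cfg.eta > 0)

    if nonneg and cfg.eta == 0.0 and traj.min() < -1e-8:
        raise IntegrationError(
            f"negative state excursion ({traj.min():.3g}) with eta = 0; "
            "reduce the integration step"
        )
    if model in ("phase_net", "phase_hyper") and cfg.wrap:
        traj = np.mod(traj + np.pi, 2 * np.pi) - np.pi

    if model == "roessler":
        layout = [[3 * i, 3 * i + 1, 3 * i + 2] for i in range(spec.N)]
    else:
        layout = [[i] for i in range(traj.shape[2])]
    meta = dict(model=model, seed=cfg.seed, eta=cfg.eta, dt=cfg.dt,
                m=cfg.m, S=cfg.S)
    if omega is not None:
        meta["omega"] = omega
    return TimeSeriesSet(segments=list(traj), dt=cfg.dt, unit_layout=layout,
                         meta=meta)


def sample(model: str, spec: NetworkSpec | None, cfg: SimConfig,
           mode: str = "distributed") -> TimeSeriesSet:
    """Simulate under one of the two sampling regimes.

    ``distributed``: S independent segments of m samples from i.i.d. initial
    conditions. ``continuous``: a single segment of length M = cfg.m (requires
    S = 1).
    """
    if mode == "continuous":
        if cfg.S != 1:
            raise ValueError("continuous sampling requires S = 1")
        return simulate(model, spec, cfg)
    if mode == "distributed":
        return simulate(model, spec, cfg)
    raise ValueError(f"unknown sampling mode {mode!r}")


def simulate_mm(spec: NetworkSpec, cfg: SimConfig) -> TimeSeriesSet:
    """Michaelis-Menten kinetics: transients toward steady state."""
    if np.any(spec.J < 0):
        raise ValueError("Michaelis-Menten couplings must be nonnegative")
    return simulate("mm", spec, cfg)


def simulate_phase(spec: NetworkSpec, cfg: SimConfig, hyper: bool = False) -> TimeSeriesSet:
    """Phase-coupled oscillators (pairwise or hypernetwork coupling)."""
    return simulate("phase_hyper" if hyper else "phase_net", spec, cfg)


def simulate_roessler(spec: NetworkSpec, cfg: SimConfig) -> TimeSeriesSet:
    """Coupled chaotic Roessler oscillators (three components per unit)."""
    return simulate("roessler", spec, cfg)


def simulate_glycolysis(cfg: SimConfig) -> TimeSeriesSet:
    """Seven-species glycolytic oscillator (fixed system, no NetworkSpec)."""
    return simulate("glycolysis", None, cfg)


def simulate_circadian(cfg: SimConfig) -> TimeSeriesSet:
    """Ten-variable PER/TIM circadian clock (fixed system, no NetworkSpec)."""
    return simulate("circadian", None, cfg)
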