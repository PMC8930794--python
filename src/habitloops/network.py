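"""Rate-coded network primitives.

The model is a collection of small populations of leaky firing-rate units
connected by signed projections.  Each unit integrates its weighted input with
an explicit Euler step,

    tau_m * dv/dt = -v + sum(inputs) + baseline + noise,
    r = gain * max(v, 0),

where ``gain`` is the dopaminergic response-modulation factor of the unit
(1 everywhere except striatal cells under pathology).  Rates are rectified and
by default unsaturated; a nominal saturation bound only parameterizes the
numerical-instability detector (see :class:`InstabilityError`).

For speed the network is flattened once into a dense signed weight matrix and
per-unit parameter vectors; the trial-level integration then runs in a
compiled kernel (:mod:`habitloops._kernels`).  A pure-numpy ``step`` is kept
as the reference implementation and for inspection in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Invalid model or pathology configuration."""


class InstabilityError(RuntimeError):
    """Numerical runaway of the dynamics.

    Raised when any state value becomes non-finite or any rate exceeds the
    instability bound (100x the nominal saturation bound).  Carries the
    population name and the simulation time at which the runaway was detected.
    """

    def __init__(self, population: str, time_ms: float):
        self.population = population
        self.time_ms = time_ms
        super().__init__(f"unstable dynamics in population '{population}' at t={time_ms:.0f} ms")


@dataclass
class RateUnitPopulation:
    """A named vector of leaky rectified rate units."""

    name: str
    size: int
    tau_m: float = 10.0
    baseline: float = 0.0
    noise_amp: float = 0.0
    # per-unit response-modulation gain (S_f); set by pathology
    gain: np.ndarray | None = None
    # assigned by Network.finalize()
    offset: int = -1

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ConfigurationError(f"population {self.name}: size must be positive")
        if self.gain is None:
            self.gain = np.ones(self.size)

    @property
    def sl(self) -> slice:
        return slice(self.offset, self.offset + self.size)


@dataclass
class Projection:
    """A weight matrix between two populations.

    ``W`` is non-negative with shape (target.size, source.size); the sign of
    the pathway is carried separately so inhibitory projections always
    contribute non-positive input.  ``base_W`` keeps the pristine weights so
    pathology scalings (e.g. reduced lateral inhibition) are idempotent.
    """

    name: str
    source: RateUnitPopulation
    target: RateUnitPopulation
    W: np.ndarray
    sign: int = 1
    gain: float = 1.0
    plastic: bool = False
    tau_w: float | None = None
    w_min: float = 0.0
    w_max: float = np.inf
    receptor: str | None = None        # 'd1' | 'd2' for three-factor rules
    base_W: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (self.target.size, self.source.size):
            raise ConfigurationError(
                f"projection {self.name}: W shape {self.W.shape} != "
                f"({self.target.size}, {self.source.size})")
        if self.sign not in (+1, -1):
            raise ConfigurationError(f"projection {self.name}: sign must be +1 or -1")
        if self.plastic and (self.tau_w is not None) and self.tau_w <= 0:
            raise ConfigurationError(f"projection {self.name}: tau_w must be positive")
        if np.any(self.W < 0):
            raise ConfigurationError(f"projection {self.name}: weights must be non-negative")
        if self.plastic:
            self.clip()
        if self.base_W is None:
            self.base_W = self.W.copy()

    def clip(self) -> None:
        np.clip(self.W, self.w_min, self.w_max, out=self.W)


class Network:
    """Flattened collection of populations and projections."""

    def __init__(self, dt: float = 1.0):
        self.dt = dt
        self.populations: dict[str, RateUnitPopulation] = {}
        self.projections: dict[str, Projection] = {}
        self._finalized = False

    # -- construction ------------------------------------------------------
    def add(self, pop: RateUnitPopulation) -> RateUnitPopulation:
        if pop.name in self.populations:
            raise ConfigurationError(f"duplicate population {pop.name}")
        self.populations[pop.name] = pop
        return pop

    def connect(self, proj: Projection) -> Projection:
        if proj.name in self.projections:
            raise ConfigurationError(f"duplicate projection {proj.name}")
        self.projections[proj.name] = proj
        return proj

    def finalize(self) -> None:
        off = 0
        for pop in self.populations.values():
            pop.offset = off
            off += pop.size
        self.n_units = off
        self.G = np.zeros((off, off))
        self.tau = np.empty(off)
        self.baseline = np.empty(off)
        self.noise_vec = np.zeros(off)
        self.gain_vec = np.ones(off)
        self._unit_pop = np.empty(off, dtype=object)
        for pop in self.populations.values():
            self.tau[pop.sl] = pop.tau_m
            self.baseline[pop.sl] = pop.baseline
            self.noise_vec[pop.sl] = pop.noise_amp
            self.gain_vec[pop.sl] = pop.gain
            for i in range(pop.offset, pop.offset + pop.size):
                self._unit_pop[i] = pop.name
        self.v = np.zeros(off)
        self.r = np.zeros(off)
        self._finalized = True
        for proj in self.projections.values():
            self.refresh(proj)
        self.reset()

    # -- weight/gain bookkeeping -------------------------------------------
    def refresh(self, proj: Projection) -> None:
        """Write a projection's signed, scaled weights into the dense matrix."""
        self.G[proj.target.sl, proj.source.sl] = proj.sign * proj.gain * proj.W

    def refresh_gains(self) -> None:
        for pop in self.populations.values():
            self.gain_vec[pop.sl] = pop.gain

    def unit_name(self, idx: int) -> str:
        return self._unit_pop[idx]

    # -- state --------------------------------------------------------------
    def reset(self) -> None:
        """Reset membrane potentials to baseline, rates to the transfer of it."""
        self.v[:] = self.baseline
        self.r[:] = self.gain_vec * np.maximum(self.v, 0.0)

    # -- reference integrator ------------------------------------------------
    def step(self, ext: np.ndarray | None = None, rng: np.random.Generator | None = None,
             noise_amp: float = 0.0, inst_bound: float = np.inf, t_ms: float = 0.0,
             saturate_bound: float | None = None) -> None:
        """One explicit Euler update (pure numpy reference).

        Raises :class:`InstabilityError` if any state is non-finite or any
        rate exceeds ``inst_bound``.
        """
        u = self.G @ self.r + self.baseline
        if ext is not None:
            u = u + ext
        dv = (self.dt / self.tau) * (u - self.v)
        if rng is not None and noise_amp > 0:
            dv = dv + rng.uniform(-noise_amp, noise_amp, self.n_units)
        self.v += dv
        np.maximum(self.v, 0.0, out=self.r)
        if saturate_bound is not None:
            np.minimum(self.r, saturate_bound, out=self.r)
        self.r *= self.gain_vec
        bad = ~np.isfinite(self.v) | ~np.isfinite(self.r) | (self.r > inst_bound)
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise InstabilityError(self.unit_name(idx), t_ms)
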