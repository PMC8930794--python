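"""Dopamine signal and the two learning rules.

Cortico-striatal projections learn with a three-factor rule gated by the
phasic dopamine deviation from baseline: a reward burst potentiates synapses
onto D1 (direct-pathway) cells and depresses synapses onto D2
(indirect-pathway) cells; a dip on reward omission does the opposite.

The cortico-thalamic shortcut learns with a Hebbian rule whose teacher is the
basal ganglia: the postsynaptic thalamic rate is already shaped by pallidal
inhibition, so learning only proceeds when the basal ganglia release the
thalamus.  The rule is pre- and post-gated with multiplicative decay toward
the postsynaptic rate,

    dW = (dt / tau_w) * pre * post * (post - W),

so non-coactive synapses are untouched, the per-synapse fixed point tracks
the thalamic teacher rate, and the per-step weight change scales exactly with
1 / tau_w (the shortcut learning-speed knob).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ConfigurationError, Projection


@dataclass
class DopamineSignal:
    """Tonic baseline plus reward-locked phasic burst/dip.

    The phasic deviation from ``tonic`` is the learning signal; lowering the
    baseline while fixing the peak is how the amplitude of the phasic response
    is increased under the plasticity-modulation pathology.
    """

    tonic: float = 0.5
    peak: float = 0.9
    dip_fraction: float = 1.0        #: dip amplitude as a fraction of the burst
    plasticity_gain: float = 1.0
    level: float = None

    def __post_init__(self):
        if self.level is None:
            self.level = self.tonic

    @property
    def burst_amplitude(self) -> float:
        return self.peak - self.tonic

    @property
    def dip_amplitude(self) -> float:
        return self.dip_fraction * self.burst_amplitude


def phasic_dopamine(rewarded: bool, da: DopamineSignal) -> float:
    """Phasic dopamine level after feedback; sets ``da.level``.

    Reward drives the level to ``peak``; omission dips it below baseline
    (floored at zero).  The deviation ``level - tonic`` gates learning.
    """
    if rewarded:
        da.level = da.peak
    else:
        da.level = max(0.0, da.tonic - da.dip_amplitude)
    return da.level


def da_deviation(da: DopamineSignal) -> float:
    return da.level - da.tonic


def update_corticostriatal(proj: Projection, pre_rates: np.ndarray,
                           post_rates: np.ndarray, da_dev: float,
                           receptor: str, lr: float,
                           plasticity_gain: float = 1.0,
                           post_threshold: float = 0.0,
                           soft_bound_gain: float = 1.2) -> Projection:
    """Three-factor update with a rate-referenced soft bound on potentiation.

    ``receptor`` selects the dopamine sign: +1 for D1 (bursts potentiate),
    -1 for D2 (bursts depress).  ``post_threshold`` is a postsynaptic activity
    threshold (covariance-style): cells that were only residually active take
    no credit, so reward does not leak onto unselected channels.

    Potentiation saturates at ``soft_bound_gain * post`` per synapse, so the
    asymptotic weight tracks the postsynaptic operating rate and the size of
    the phasic dopamine deviation only sets the approach speed.  Depression is
    linear.  Weights are clipped to the projection bounds.
    """
    if not proj.plastic:
        return proj
    sign = {"d1": 1.0, "d2": -1.0}[receptor.lower()]
    post = np.maximum(post_rates - post_threshold, 0.0)
    drive = sign * da_dev
    if drive >= 0:
        headroom = np.maximum(soft_bound_gain * post_rates[:, None] - proj.W, 0.0)
        dw = lr * plasticity_gain * drive * (post[:, None] * pre_rates[None, :]) * headroom
    else:
        dw = lr * plasticity_gain * drive * np.outer(post, pre_rates)
    proj.W += dw
    proj.clip()
    return proj


def update_shortcut(shortcut: Projection, pre_cortex_rates: np.ndarray,
                    thalamus_rates: np.ndarray, dt: float,
                    target_gain: float = 1.0) -> Projection:
    """Basal-ganglia-gated Hebbian shortcut update (no-op if not plastic).

    ``target_gain`` scales the fixed point relative to the thalamic teacher
    rate (synaptic efficacy saturates below a one-to-one transfer).
    """
    if not shortcut.plastic:
        return shortcut
    if shortcut.tau_w is None or shortcut.tau_w <= 0:
        raise ConfigurationError("shortcut tau_w must be positive when plastic")
    post = thalamus_rates[:, None]
    pre = pre_cortex_rates[None, :]
    shortcut.W += (dt / shortcut.tau_w) * pre * post * (target_gain * post - shortcut.W)
    shortcut.clip()
    return shortcut
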