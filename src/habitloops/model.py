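"""The hierarchical two-loop model.

Two cortico-basal-ganglia-thalamo-cortical loops are wired from rate-unit
populations:

* a **cognitive loop** (dorsomedial striatum): stimulus and goal cortex drive
  D1/D2 medium spiny neurons, which select a cognitive category through the
  direct (D1 -> GPi), indirect (D2 -> GPe -> GPi) and hyperdirect
  (cortex -> STN -> GPi) pathways, pallido-thalamic disinhibition and a
  thalamo-cortical amplifier;
* a **motor loop** (dorsolateral striatum): the selected category reaches the
  motor striatum through overlapping cortico-striatal projections (the
  *crosslink*) and the loop selects a LEFT or RIGHT button press read from
  motor cortex.

A plastic **cortico-thalamic shortcut** connects stimulus cortex directly to
the motor thalamus, bypassing the cognitive loop; motor cortex projects back
to a dedicated group of motor D1 cells (the *feedback* pathway), closing a
loop through the direct pathway that amplifies shortcut-initiated activity.
Habitual responding to devalued outcomes emerges when the trained shortcut
ignites this loop although the cognitive loop is silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .network import (ConfigurationError, InstabilityError, Network,
                      Projection, RateUnitPopulation)
from .params import DEFAULT_PARAMS, ModelParams
from .pathology import PathologyConfig, apply_pathology
from .plasticity import (DopamineSignal, da_deviation, phasic_dopamine,
                         update_corticostriatal, update_shortcut)
from .task import NONE, InputDrive, TaskSpec, response_name

COG_POPS = ("cog_d1", "cog_d2", "cog_stn", "cog_gpe", "cog_gpi", "cog_thal", "cog_ctx")
MOT_POPS = ("mot_d1_cl", "mot_d1_fb", "mot_d2", "mot_stn", "mot_gpe", "mot_gpi",
            "mot_thal", "mot_ctx")


@dataclass
class LoopModel:
    """Named handles onto one loop's populations."""

    cortex_in: tuple
    striatum_d1: tuple
    striatum_d2: str
    stn: str
    gpe: str
    gpi: str
    thalamus: str
    cortex_out: str


@dataclass
class TrialOutcome:
    response: str
    rt_ms: float
    unstable: bool = False
    unstable_population: str | None = None
    unstable_time_ms: float = np.nan


class HierarchicalModel:
    """Assembled network plus plasticity state for one simulated subject."""

    def __init__(self, net: Network, params: ModelParams, task: TaskSpec,
                 pathology: PathologyConfig, seed: int):
        self.net = net
        self.params = params
        self.task = task
        self.seed = seed
        self.pathology = pathology
        self.dopamine_cog = DopamineSignal(tonic=pathology.da_tonic, peak=pathology.da_peak)
        self.dopamine_mot = DopamineSignal(tonic=pathology.da_tonic, peak=pathology.da_peak)
        self.rng = np.random.default_rng(seed)
        self.cognitive_loop = LoopModel(
            cortex_in=("stim", "goal"), striatum_d1=("cog_d1",), striatum_d2="cog_d2",
            stn="cog_stn", gpe="cog_gpe", gpi="cog_gpi", thalamus="cog_thal",
            cortex_out="cog_ctx")
        self.motor_loop = LoopModel(
            cortex_in=("cog_ctx",), striatum_d1=("mot_d1_cl", "mot_d1_fb"),
            striatum_d2="mot_d2", stn="mot_stn", gpe="mot_gpe", gpi="mot_gpi",
            thalamus="mot_thal", cortex_out="mot_ctx")
        # groups used by pathology transforms
        self.dms_lateral = ("cog_d1_lat", "cog_d2_lat")
        self.dls_lateral = ("mot_d1_cl_lat", "mot_d1_fb_cl_lat", "mot_d2_lat")
        self.d1_populations = ("cog_d1", "mot_d1_cl", "mot_d1_fb")
        self.d2_populations = ("cog_d2", "mot_d2")
        # plastic cortico-striatal projections: (name, pre pop, post pop, receptor, loop)
        self.corticostriatal = (
            ("stim_cog_d1", "stim", "cog_d1", "d1", "cog"),
            ("goal_cog_d1", "goal", "cog_d1", "d1", "cog"),
            ("stim_cog_d2", "stim", "cog_d2", "d2", "cog"),
            ("goal_cog_d2", "goal", "cog_d2", "d2", "cog"),
            ("crosslink", "cog_ctx", "mot_d1_cl", "d1", "mot"),
            ("crosslink_d2", "cog_ctx", "mot_d2", "d2", "mot"),
        )
        self.last_outcome: TrialOutcome | None = None
        self._last_avg: np.ndarray | None = None

    # -- convenience accessors ----------------------------------------------
    @property
    def shortcut(self) -> Projection:
        return self.net.projections["shortcut"]

    @property
    def feedback(self) -> Projection:
        return self.net.projections["feedback"]

    @property
    def crosslink(self) -> Projection:
        return self.net.projections["crosslink"]

    def rates(self, pop: str) -> np.ndarray:
        return self.net.r[self.net.populations[pop].sl]

    # -- trial machinery ------------------------------------------------------
    def _ext_vector(self, drive: InputDrive) -> np.ndarray:
        p = self.params
        ext = np.zeros(self.net.n_units)
        ext[self.net.populations["stim"].sl] = p.stim_amplitude * drive.stim
        ext[self.net.populations["goal"].sl] = p.goal_amplitude * drive.goal
        return ext

    def _phase(self, ext: np.ndarray, n_steps: int, detect: bool = False,
               collect: bool = False, t0: float = 0.0):
        p = self.params
        net = self.net
        mctx = net.populations["mot_ctx"]
        avg = np.zeros(net.n_units) if collect else np.zeros(0)
        thr_lo, thr_hi = (mctx.offset, mctx.offset + mctx.size) if detect else (0, 0)
        threshold = p.decision_threshold if detect else 0.0
        status, steps, unit = _kernels.run_phase(
            net.G, net.v, net.r, net.tau, net.baseline, net.gain_vec, ext,
            p.dt, n_steps, net.noise_vec, thr_lo, thr_hi, threshold,
            avg, collect, p.instability_bound, t0)
        return status, steps, unit, avg

    def run_trial_selection(self, drive: InputDrive) -> TrialOutcome:
        """Settle, present the inputs and read the first threshold crossing.

        Returns the response (NONE on timeout).  Numerical runaways are
        reported in the outcome rather than raised, so a cohort run can record
        them per subject.
        """
        p = self.params
        self.net.reset()
        zeros = np.zeros(self.net.n_units)
        status, steps, unit, _ = self._phase(zeros, int(p.settle_ms / p.dt))
        t = steps * p.dt
        if status == _kernels.UNSTABLE:
            out = TrialOutcome(NONE, np.nan, True, self.net.unit_name(unit), t)
            self.last_outcome = out
            return out
        ext = self._ext_vector(drive)
        status, steps, unit, _ = self._phase(ext, int(p.selection_ms / p.dt), detect=True)
        rt = steps * p.dt
        if status == _kernels.UNSTABLE:
            out = TrialOutcome(NONE, np.nan, True, self.net.unit_name(unit), t + rt)
        elif status == _kernels.CROSSED:
            out = TrialOutcome(response_name(unit), rt)
        else:
            out = TrialOutcome(NONE, np.nan)
        self.last_outcome = out
        return out

    def run_learning_window(self, drive: InputDrive, rewarded: bool,
                            learn: bool, responded: bool = True) -> TrialOutcome | None:
        """Post-feedback window: integrate, then apply plasticity once.

        Cortico-striatal projections use the three-factor rule with the
        phasic dopamine deviation of their loop; the shortcut uses the
        Hebbian rule with the window duration as its effective time step.
        Returns an unstable TrialOutcome if a runaway occurred, else None.
        """
        p = self.params
        ext = self._ext_vector(drive)
        status, steps, unit, avg = self._phase(ext, int(p.learning_ms / p.dt), collect=True)
        if status == _kernels.UNSTABLE:
            return TrialOutcome(NONE, np.nan, True, self.net.unit_name(unit), steps * p.dt)
        self._last_avg = avg
        if not learn:
            return None
        if responded:
            # withheld responses produce no outcome and no phasic dopamine
            phasic_dopamine(rewarded, self.dopamine_cog)
            phasic_dopamine(rewarded, self.dopamine_mot)
        net = self.net
        for name, pre, post, receptor, loop in self.corticostriatal:
            da = self.dopamine_cog if loop == "cog" else self.dopamine_mot
            lr = p.lr_cognitive if loop == "cog" else p.lr_crosslink
            if loop == "cog" and receptor == "d1" and da_deviation(da) < 0:
                lr *= p.cog_d1_dip_scale
            if loop == "cog" and receptor == "d2" and da_deviation(da) > 0:
                lr *= p.cog_d2_burst_scale
            proj = net.projections[name]
            update_corticostriatal(
                proj, avg[net.populations[pre].sl], avg[net.populations[post].sl],
                da_deviation(da), receptor, lr, da.plasticity_gain,
                post_threshold=p.plasticity_post_threshold,
                soft_bound_gain=p.plasticity_soft_bound_gain)
            net.refresh(proj)
        sc = self.shortcut
        if sc.plastic:
            update_shortcut(sc, avg[net.populations["stim"].sl],
                            avg[net.populations["mot_thal"].sl], p.learning_ms,
                            target_gain=p.shortcut_target_gain)
            net.refresh(sc)
        self.dopamine_cog.level = self.dopamine_cog.tonic
        self.dopamine_mot.level = self.dopamine_mot.tonic
        return None


# -- spec-level operations ----------------------------------------------------

def apply_gain(v: float, s_f: float, receptor: str = "d1") -> float:
    """Rectifying transfer with response modulation.

    D1 cells: ``rate = s_f * max(v, 0)``; D2 cells: ``rate = max(v, 0) / s_f``
    (higher tonic dopamine excites the direct and inhibits the indirect
    pathway).  ``s_f = 1`` reproduces the unmodulated transfer exactly.
    """
    if s_f <= 0:
        raise ConfigurationError("s_f must be positive")
    r = max(v, 0.0)
    return r * s_f if receptor.lower() == "d1" else r / s_f


def read_response(model: HierarchicalModel) -> str:
    """Response of the last simulated trial window (LEFT/RIGHT/NONE)."""
    if model.last_outcome is None:
        raise RuntimeError("no trial has been simulated yet")
    return model.last_outcome.response


def step(model: HierarchicalModel, inputs: InputDrive, dt: float) -> HierarchicalModel:
    """One explicit Euler update of every population (reference path).

    Raises :class:`habitloops.network.InstabilityError` on any non-finite
    state or runaway rate.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    net = model.net
    old_dt = net.dt
    net.dt = dt
    try:
        net.step(ext=model._ext_vector(inputs), rng=model.rng,
                 noise_amp=model.params.noise_amp,
                 inst_bound=model.params.instability_bound)
    finally:
        net.dt = old_dt
    return model


def _identity(n: int, w: float) -> np.ndarray:
    return w * np.eye(n)


def _offdiag(n: int, w: float) -> np.ndarray:
    return w * (np.ones((n, n)) - np.eye(n))


def _cross_channel(n: int, w: float) -> np.ndarray:
    return w * (np.ones((n, n)) - np.eye(n))


def build_model(task: TaskSpec, pathology: PathologyConfig, seed: int,
                params: ModelParams | None = None) -> HierarchicalModel:
    """Construct and wire the full hierarchical model.

    The same (task, pathology, seed) yields bit-identical initial weights.
    The control wiring is built first and the pathology transform applied on
    top, so ``preset("control")`` is an exact no-op.
    """
    p = params if params is not None else DEFAULT_PARAMS
    rng = np.random.default_rng(seed)
    net = Network(dt=p.dt)
    ns, ng, nc, nr = p.n_stimuli, p.n_goals, p.n_categories, p.n_responses

    def pop(name, size, baseline=0.0, noise=None):
        return net.add(RateUnitPopulation(name, size, tau_m=p.tau_m, baseline=baseline,
                                          noise_amp=p.noise_amp if noise is None else noise))

    pop("stim", ns)
    pop("goal", ng)
    pop("cog_d1", nc)
    pop("cog_d2", nc)
    pop("cog_stn", nc)
    pop("cog_gpe", nc, p.cog_gpe_base)
    pop("cog_gpi", nc, p.cog_gpi_base, noise=p.noise_amp_cog_gpi)
    pop("cog_thal", nc, p.cog_thal_base)
    pop("cog_ctx", nc)
    pop("mot_d1_cl", nr)
    pop("mot_d1_fb", nr)
    pop("mot_d2", nr)
    pop("mot_stn", nr)
    pop("mot_gpe", nr, p.mot_gpe_base)
    pop("mot_gpi", nr, p.mot_gpi_base)
    pop("mot_thal", nr, p.mot_thal_base)
    pop("mot_ctx", nr)

    P = net.populations

    def proj(name, src, tgt, W, sign=1, **kw):
        return net.connect(Projection(name, P[src], P[tgt], W, sign=sign, **kw))

    def u(lo_hi, shape):
        lo, hi = lo_hi
        return rng.uniform(lo, hi, shape)

    # cognitive loop -- plastic cortico-striatal inputs; the stimulus stream is
    # initialized topographically (diagonal preference, see params)
    W_sd1 = u(p.cog_stim_off_init, (nc, ns))
    np.fill_diagonal(W_sd1, u(p.cog_stim_diag_init, min(nc, ns)))
    proj("stim_cog_d1", "stim", "cog_d1", W_sd1, receptor="d1",
         plastic=True, w_min=p.w_cog_d1_min, w_max=p.w_cog_stim_max)
    proj("goal_cog_d1", "goal", "cog_d1", u(p.cog_goal_init, (nc, ng)), receptor="d1",
         plastic=True, w_min=p.w_cog_d1_min, w_max=p.w_cog_goal_max)
    proj("stim_cog_d2", "stim", "cog_d2", u(p.cog_d2_init, (nc, ns)), receptor="d2",
         plastic=True, w_min=0.0, w_max=p.w_cog_stim_max)
    proj("goal_cog_d2", "goal", "cog_d2", u(p.cog_d2_init, (nc, ng)), receptor="d2",
         plastic=True, w_min=0.0, w_max=p.w_cog_goal_max)
    # local striatal inhibition (the DMS disinhibition target)
    proj("cog_d1_lat", "cog_d1", "cog_d1", _offdiag(nc, p.w_cog_lat), sign=-1)
    proj("cog_d2_lat", "cog_d2", "cog_d2", _offdiag(nc, p.w_cog_lat), sign=-1)
    # direct / indirect / hyperdirect pathways
    proj("stim_cog_stn", "stim", "cog_stn", _identity(ns, p.w_cog_stim_stn))
    proj("cog_stn_gpi", "cog_stn", "cog_gpi", np.full((nc, nc), p.w_cog_stn_gpi))
    proj("cog_d1_gpi", "cog_d1", "cog_gpi", _identity(nc, p.w_cog_d1_gpi), sign=-1)
    proj("cog_d2_gpe", "cog_d2", "cog_gpe", _identity(nc, p.w_cog_d2_gpe), sign=-1)
    proj("cog_gpe_gpi", "cog_gpe", "cog_gpi", _identity(nc, p.w_cog_gpe_gpi), sign=-1)
    proj("cog_gpi_thal", "cog_gpi", "cog_thal", _identity(nc, p.w_cog_gpi_thal), sign=-1)
    proj("cog_thal_ctx", "cog_thal", "cog_ctx", _identity(nc, p.w_cog_thal_ctx))
    proj("cog_ctx_thal", "cog_ctx", "cog_thal", _identity(nc, p.w_cog_ctx_thal))
    # closed-loop cortical feedback: lets a tentatively selected category
    # amplify itself so the striatal competition resolves to a single winner
    proj("cog_ctx_d1", "cog_ctx", "cog_d1", _identity(nc, p.w_cog_ctx_d1))
    proj("cog_ctx_d2", "cog_ctx", "cog_d2", _identity(nc, p.w_cog_ctx_d1))
    proj("cog_ctx_lat", "cog_ctx", "cog_ctx", _offdiag(nc, p.w_cog_ctx_lat), sign=-1)

    # motor loop
    mot_kw = dict(plastic=True, w_min=0.0, w_max=p.w_mot_cs_max)
    proj("crosslink", "cog_ctx", "mot_d1_cl", u(p.crosslink_d1_init, (nr, nc)),
         receptor="d1", plastic=True, w_min=p.w_crosslink_d1_min, w_max=p.w_mot_cs_max)
    proj("crosslink_d2", "cog_ctx", "mot_d2", u(p.crosslink_d2_init, (nr, nc)),
         receptor="d2", **mot_kw)
    proj("feedback", "mot_ctx", "mot_d1_fb", _identity(nr, p.w_feedback))
    # NoGo cells are co-activated by the selected action's cortical feedback,
    # so omission dips penalize the action that was actually taken
    proj("feedback_d2", "mot_ctx", "mot_d2", _identity(nr, p.w_feedback_d2))
    proj("shortcut", "stim", "mot_thal", np.full((nr, ns), p.shortcut_init),
         plastic=True, tau_w=pathology.shortcut_tau_w, gain=p.shortcut_gain,
         w_min=0.0, w_max=p.shortcut_w_max)
    # lateral inhibition: feedback-recipient D1 cells inhibit but are not
    # themselves inhibited, so the cortex-striatum-pallidum-thalamus loop can
    # amplify a candidate response that the crosslink alone leaves subthreshold
    proj("mot_d1_cl_lat", "mot_d1_cl", "mot_d1_cl", _cross_channel(nr, p.w_mot_lat), sign=-1)
    proj("mot_d1_fb_cl_lat", "mot_d1_fb", "mot_d1_cl", _cross_channel(nr, p.w_mot_lat), sign=-1)
    proj("mot_d2_lat", "mot_d2", "mot_d2", _cross_channel(nr, p.w_mot_d2_lat), sign=-1)
    proj("cog_ctx_mot_stn", "cog_ctx", "mot_stn", np.full((nr, nc), p.w_mot_ctx_stn))
    proj("mot_stn_gpi", "mot_stn", "mot_gpi", np.full((nr, nr), p.w_mot_stn_gpi))
    proj("mot_d1_cl_gpi", "mot_d1_cl", "mot_gpi", _identity(nr, p.w_mot_d1_gpi), sign=-1)
    proj("mot_d1_fb_gpi", "mot_d1_fb", "mot_gpi", _identity(nr, p.w_mot_d1_gpi), sign=-1)
    proj("mot_d2_gpe", "mot_d2", "mot_gpe", _identity(nr, p.w_mot_d2_gpe), sign=-1)
    proj("mot_gpe_gpi", "mot_gpe", "mot_gpi", _identity(nr, p.w_mot_gpe_gpi), sign=-1)
    proj("mot_gpi_thal", "mot_gpi", "mot_thal", _identity(nr, p.w_mot_gpi_thal), sign=-1)
    proj("mot_thal_ctx", "mot_thal", "mot_ctx", _identity(nr, p.w_mot_thal_ctx))
    proj("mot_ctx_lat", "mot_ctx", "mot_ctx", _cross_channel(nr, p.w_mot_ctx_lat), sign=-1)
    proj("mot_ctx_thal", "mot_ctx", "mot_thal", _identity(nr, p.w_mot_ctx_thal))

    net.finalize()
    model = HierarchicalModel(net, p, task, pathology, seed)
    apply_pathology(model, pathology)
    return model
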