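"""Fixed parameters of the two-loop rate model.

All weights are dimensionless synaptic efficacies; time constants are in
milliseconds.  The values below define the *control* (healthy) model.  They
were calibrated once against the behavioral constraints the model is meant to
reproduce (training performance above 90% after eight 12-trial blocks, low but
non-zero responding to devalued outcomes in the control model, reliable
responding in early training) and are not intended to be moved per experiment;
every pathological manipulation is expressed through
:class:`habitloops.pathology.PathologyConfig` instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ModelParams:
    """Parameters of the hierarchical cortico-basal-ganglia model."""

    # --- integration -----------------------------------------------------
    dt: float = 1.0                 #: Euler step (ms)
    tau_m: float = 10.0             #: membrane time constant, all populations (ms)
    noise_amp: float = 0.01         #: half-width of per-step uniform membrane noise
    #: pallidal output noise: trial-to-trial variability of the selection gate
    noise_amp_cog_gpi: float = 0.03

    # --- transfer function ----------------------------------------------
    #: nominal saturation bound of the rectifying transfer.  Rates are *not*
    #: clipped by default (``saturate=False``); the bound is the reference
    #: scale of the instability detector (rates beyond ``100 * rate_sat`` are
    #: classified as a numerical runaway).
    rate_sat: float = 1.2
    saturate: bool = False
    instability_factor: float = 100.0

    # --- trial structure --------------------------------------------------
    settle_ms: int = 150            #: relaxation to rest before stimulus onset
    selection_ms: int = 2000        #: maximum stimulus window for a response
    learning_ms: int = 1000         #: post-feedback window; plasticity uses its mean rates
    decision_threshold: float = 1.0  #: motor-cortex rate that counts as a button press

    # --- layer sizes ------------------------------------------------------
    n_stimuli: int = 6
    n_goals: int = 6
    n_categories: int = 6
    n_responses: int = 2

    # --- cognitive (dorsomedial) loop ------------------------------------
    #: topographic initialization of stimulus -> D1: each stimulus starts with
    #: a preferred (diagonal) category so cortico-striatal exploration is a
    #: per-category button bandit rather than a 6x6 assignment problem
    cog_stim_diag_init: tuple = (0.32, 0.42)
    cog_stim_off_init: tuple = (0.15, 0.25)
    cog_goal_init: tuple = (0.32, 0.40)
    cog_d2_init: tuple = (0.30, 0.50)
    w_cog_lat: float = 0.12             #: lateral inhibition among DMS units (off-diagonal)
    w_cog_stim_max: float = 0.42        #: cap per stimulus -> striatum entry
    w_cog_goal_max: float = 0.40        #: cap per goal -> striatum entry
    w_cog_stim_stn: float = 0.3
    w_cog_stn_gpi: float = 0.3
    w_cog_d1_gpi: float = 2.2
    w_cog_d2_gpe: float = 1.0
    w_cog_gpe_gpi: float = 0.3
    w_cog_gpi_thal: float = 0.5
    w_cog_thal_ctx: float = 2.0
    w_cog_ctx_thal: float = 0.4
    w_cog_ctx_d1: float = 0.3          #: closed-loop cortical feedback onto DMS D1
    w_cog_ctx_lat: float = 0.35         #: competition among category-cortex units
    cog_gpe_base: float = 1.0
    cog_gpi_base: float = 1.23
    cog_thal_base: float = 0.1

    # --- motor (dorsolateral) loop ----------------------------------------
    crosslink_d1_init: tuple = (0.40, 0.60)
    crosslink_d2_init: tuple = (0.30, 0.50)
    #: cap for the overlapping cortico-striatal (crosslink) weights.  The cap
    #: is far above the healthy operating range on purpose: with intact
    #: lateral inhibition the weights are bounded dynamically by competition,
    #: and a tight cap would mask the runaway that full striatal
    #: disinhibition is documented to produce.
    w_mot_cs_max: float = 50.0
    w_mot_lat: float = 0.45             #: lateral inhibition among DLS D1 units (cross-channel)
    w_mot_d2_lat: float = 0.7           #: lateral inhibition among DLS D2 units
    w_feedback: float = 0.29            #: motor cortex -> feedback-recipient D1 cells
    w_mot_ctx_stn: float = 0.3
    w_mot_stn_gpi: float = 0.3
    w_mot_d1_gpi: float = 2.6
    w_mot_d2_gpe: float = 1.5
    w_mot_gpe_gpi: float = 0.5
    w_mot_gpi_thal: float = 0.95
    w_mot_thal_ctx: float = 2.0
    w_mot_ctx_thal: float = 0.02
    w_mot_ctx_lat: float = 0.35         #: motor-cortex response competition
    w_feedback_d2: float = 0.35         #: motor cortex -> DLS D2 (ties NoGo cells to the selected action)
    mot_gpe_base: float = 1.0
    mot_gpi_base: float = 1.4
    mot_thal_base: float = 0.486

    # --- cortico-thalamic shortcut ----------------------------------------
    shortcut_init: float = 0.42          #: uniform initial shortcut efficacy
    shortcut_gain: float = 0.45          #: fixed pathway gain multiplying the plastic W
    shortcut_w_max: float = 1.2
    shortcut_target_gain: float = 1.20  #: fixed-point scale relative to the thalamic teacher

    # --- plasticity --------------------------------------------------------
    #: three-factor learning rates (per trial).  The crosslink (category ->
    #: button) must adapt faster than the cognitive assignment so a wrong
    #: button flips before dips erode the category itself.
    lr_cognitive: float = 0.06
    lr_crosslink: float = 0.32
    #: dopamine dips act on the cognitive loop through the indirect (D2)
    #: pathway only: D1 stimulus/goal associations are not unlearned by
    #: omissions, so the acquired task representation cannot be erased by a
    #: run of errors (selection is re-biased via D2 instead)
    cog_d1_dip_scale: float = 0.0
    #: likewise, bursts do not erase the cognitive indirect pathway: the
    #: trained channel's NoGo threshold stays put, preserving the goal gate
    cog_d2_burst_scale: float = 0.0
    #: postsynaptic activity threshold of the three-factor rule; residually
    #: active (unselected) striatal cells take no credit
    plasticity_post_threshold: float = 0.4
    #: potentiation saturates at this multiple of the postsynaptic rate
    plasticity_soft_bound_gain: float = 1.2
    #: weight floors on D1-stream plastic projections: omission dips may not
    #: erase an action below its functional range, so an unrewarded option
    #: remains recoverable once the competing habit is suppressed
    w_cog_d1_min: float = 0.15
    w_crosslink_d1_min: float = 0.30

    # --- task encoding ------------------------------------------------------
    stim_amplitude: float = 1.0
    goal_amplitude: float = 0.85
    stim_attenuation: float = 0.25      #: stimulus drive on stimulus-devalued trials

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.tau_m <= 0:
            raise ValueError("dt and tau_m must be positive")

    @property
    def instability_bound(self) -> float:
        """Rate above which the dynamics count as numerically unstable."""
        return self.instability_factor * self.rate_sat


DEFAULT_PARAMS = ModelParams()
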