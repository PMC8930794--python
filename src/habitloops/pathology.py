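"""Pathological manipulations as validated, named configurations.

Every manipulation studied with the model is one knob of
:class:`PathologyConfig`:

* ``shortcut_tau_w`` / ``shortcut_plastic`` — learning speed of the
  cortico-thalamic shortcut (smaller time constant = faster habit learning),
  or no shortcut learning at all.
* ``sf`` / ``feedback_modulated`` — tonic-dopamine response modulation of
  striatal cells: rates of D1 cells are multiplied by ``sf`` and rates of D2
  cells divided by it.  With ``feedback_modulated=False`` (model B) the gain
  is removed from exactly those motor-striatum cells that receive cortical
  feedback, isolating the shortcut-feedback pathway.
* ``da_peak`` / ``da_tonic`` — amplitude of the phasic dopamine response used
  by the plasticity rule; the baseline is lowered as the peak is raised so
  larger peaks mean larger phasic deviations.
* ``dms_inhibition`` / ``dls_inhibition`` — fraction of the control lateral
  inhibitory weights kept within the dorsomedial / dorsolateral striatum
  (1.0 = control, 0.0 = no local inhibition).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, asdict, replace

import yaml

from .network import ConfigurationError

CONTROL_TAU_W = 15000.0
CONTROL_DA_PEAK = 0.9
CONTROL_DA_TONIC = 0.5


@dataclass(frozen=True)
class PathologyConfig:
    name: str = "control"
    shortcut_plastic: bool = True
    shortcut_tau_w: float = CONTROL_TAU_W
    sf: float = 1.0
    feedback_modulated: bool = True
    da_peak: float = CONTROL_DA_PEAK
    da_tonic: float = CONTROL_DA_TONIC
    dms_inhibition: float = 1.0
    dls_inhibition: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.dms_inhibition <= 1.0 and 0.0 <= self.dls_inhibition <= 1.0):
            raise ConfigurationError("inhibition fractions must lie in [0, 1]")
        if self.sf <= 0:
            raise ConfigurationError("sf must be positive")
        if self.shortcut_plastic and self.shortcut_tau_w <= 0:
            raise ConfigurationError("shortcut_tau_w must be positive when plastic")
        if not (0.0 <= self.da_tonic <= self.da_peak):
            raise ConfigurationError("need 0 <= da_tonic <= da_peak")


CONTROL = PathologyConfig()

_PARAM_RE = re.compile(r"^([a-z_]+)\(([-0-9.]+)\)$")


def preset(name: str) -> PathologyConfig:
    """Named configuration; parameterized presets use ``name(value)`` syntax.

    Examples: ``control``, ``fast_shortcut_6000``, ``no_shortcut_plasticity``,
    ``da_response_mod(1.02)``, ``da_response_mod_no_feedback(1.02)``,
    ``da_plasticity_mod(1.0)``, ``reduced_dms(0.4)``, ``reduced_dls(0.8)``.
    """
    fixed = {
        "control": CONTROL,
        "fast_shortcut_6000": replace(CONTROL, name=name, shortcut_tau_w=6000.0),
        "shortcut_12000": replace(CONTROL, name=name, shortcut_tau_w=12000.0),
        "shortcut_14000": replace(CONTROL, name=name, shortcut_tau_w=14000.0),
        "no_shortcut_plasticity": replace(CONTROL, name=name, shortcut_plastic=False),
    }
    if name in fixed:
        return fixed[name]
    m = _PARAM_RE.match(name.replace(" ", ""))
    if not m:
        raise KeyError(f"unknown preset {name!r}")
    kind, value = m.group(1), float(m.group(2))
    if kind == "da_response_mod":
        return replace(CONTROL, name=name, sf=value)
    if kind == "da_response_mod_no_feedback":
        return replace(CONTROL, name=name, sf=value, feedback_modulated=False)
    if kind == "da_plasticity_mod":
        # the baseline is lowered by the amount the peak is raised, so the
        # phasic deviation grows twice as fast as the peak itself
        tonic = CONTROL_DA_TONIC - (value - CONTROL_DA_PEAK)
        return replace(CONTROL, name=name, da_peak=value, da_tonic=tonic)
    if kind == "reduced_dms":
        return replace(CONTROL, name=name, dms_inhibition=value)
    if kind == "reduced_dls":
        return replace(CONTROL, name=name, dls_inhibition=value)
    raise KeyError(f"unknown preset {name!r}")


PRESET_NAMES = [
    "control", "fast_shortcut_6000", "shortcut_12000", "shortcut_14000",
    "no_shortcut_plasticity", "da_response_mod(sf)",
    "da_response_mod_no_feedback(sf)", "da_plasticity_mod(peak)",
    "reduced_dms(frac)", "reduced_dls(frac)",
]


def apply_pathology(model, config: PathologyConfig):
    """Transform a freshly built model in place; idempotent.

    Scales the lateral inhibitory weights of the dorsomedial and dorsolateral
    striatum from their pristine values, installs the shortcut learning
    parameters, sets the striatal response-modulation gains (removing the gain
    from feedback-recipient motor D1 cells when ``feedback_modulated`` is
    false) and the dopamine signal parameters.
    """
    net = model.net
    for pname in model.dms_lateral:
        proj = net.projections[pname]
        proj.W = proj.base_W * config.dms_inhibition
        net.refresh(proj)
    for pname in model.dls_lateral:
        proj = net.projections[pname]
        proj.W = proj.base_W * config.dls_inhibition
        net.refresh(proj)

    shortcut = net.projections["shortcut"]
    shortcut.plastic = config.shortcut_plastic
    shortcut.tau_w = config.shortcut_tau_w

    for pop_name in model.d1_populations:
        pop = net.populations[pop_name]
        pop.gain[:] = config.sf
    for pop_name in model.d2_populations:
        pop = net.populations[pop_name]
        pop.gain[:] = 1.0 / config.sf
    if not config.feedback_modulated:
        # model B: cells receiving the cortical feedback projection (the
        # feedback D1 group and the NoGo cells) keep the unmodulated transfer
        net.populations["mot_d1_fb"].gain[:] = 1.0
        net.populations["mot_d2"].gain[:] = 1.0
    net.refresh_gains()

    for da in (model.dopamine_cog, model.dopamine_mot):
        da.tonic = config.da_tonic
        da.peak = config.da_peak
        da.level = config.da_tonic
    model.pathology = config
    return model


# -- flat key:value config files -------------------------------------------

def config_to_file(config: PathologyConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, default_flow_style=False, sort_keys=True)


def config_from_file(path) -> PathologyConfig:
    """Read a flat key:value config; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a flat key:value mapping")
    allowed = set(PathologyConfig.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")
    return PathologyConfig(**data)
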