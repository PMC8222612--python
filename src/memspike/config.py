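"""Run configuration (YAML), strict-schema parsing and named fixtures.

A run configuration collects everything a simulation needs: the circuit
parameters, an optional scenario (model form, initial state, time span),
a stimulus program (inline pulse list or CSV file reference), an optional
spike-design section and integration settings.  Parsing is strict:
unknown keys are rejected with the offending section named, and referenced
stimulus files must exist at load time.  YAML is the single supported
config format.

The fixture catalog packages the scenarios used throughout the package
documentation and tests:

* ``reference``             -- the reference parameter set alone;
* ``pulse-to-equilibrium``  -- a single area-0.5 pulse that moves the
  state between two stable-equilibrium manifolds;
* ``pulse-to-oscillation``  -- the same pulse with area 2.5, landing on a
  limit-cycle manifold;
* ``spike``                 -- the designed single-spike set/reset program;
* ``burst``                 -- three 8-spike bursts.

The ``seed`` key is reserved for forward compatibility: the whole pipeline
is deterministic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .circuit import REFERENCE_PARAMS, CircuitParams
from .pulse_design import (
    EMPTY_STIMULUS,
    Pulse,
    StimulusProgram,
    build_stimulus,
    design_spike,
)
from .simulator import IntegrationSettings

__all__ = [
    "CONFIG_VERSION",
    "Scenario",
    "DesignSpec",
    "RunConfig",
    "load_config",
    "save_config",
    "fixture",
    "FIXTURE_NAMES",
]

CONFIG_VERSION = 1


class ConfigError(ValueError):
    """Raised on schema violations, naming the offending section/field."""


def _check_keys(section: str, data: dict, allowed: set[str]) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{section}'; "
            f"allowed: {sorted(allowed)}"
        )


@dataclass(frozen=True)
class Scenario:
    """What to integrate: model form, initial state and time span."""

    form: str = "qcoords"
    initial: tuple[float, float, float] = (0.0, 0.0, 0.0)
    t_span: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        if self.form not in ("full", "qcoords", "manifold"):
            raise ConfigError(f"unknown scenario form {self.form!r}")
        if len(self.initial) != 3:
            raise ConfigError("scenario initial state must have three components")
        if not self.t_span[1] > self.t_span[0]:
            raise ConfigError(f"scenario t_span must be increasing, got {self.t_span}")


@dataclass(frozen=True)
class DesignSpec:
    """Spike-design inputs: width fraction, spikes per burst, set times."""

    sigma: float = 0.02
    n_spikes: int = 1
    set_times: tuple[float, ...] = (0.0,)


@dataclass(frozen=True)
class RunConfig:
    params: CircuitParams = REFERENCE_PARAMS
    scenario: Scenario | None = None
    stimulus: StimulusProgram = EMPTY_STIMULUS
    design: DesignSpec | None = None
    settings: IntegrationSettings = IntegrationSettings()
    seed: int = 0


def _config_from_dict(data: dict, base_dir: Path) -> RunConfig:
    _check_keys(
        "<root>",
        data,
        {"version", "params", "scenario", "stimulus", "design", "settings", "seed"},
    )
    if "params" not in data:
        raise ConfigError("missing required section 'params'")
    params_d = dict(data["params"])
    _check_keys("params", params_d, {"R", "L", "C", "s0", "s1"})
    params = CircuitParams(**{k: float(v) for k, v in params_d.items()})

    scenario = None
    if data.get("scenario") is not None:
        sc = dict(data["scenario"])
        _check_keys("scenario", sc, {"form", "initial", "t_span"})
        scenario = Scenario(
            form=sc.get("form", "qcoords"),
            initial=tuple(float(v) for v in sc.get("initial", (0.0, 0.0, 0.0))),
            t_span=tuple(float(v) for v in sc.get("t_span", (0.0, 100.0))),
        )

    stimulus = EMPTY_STIMULUS
    if data.get("stimulus") is not None:
        st = dict(data["stimulus"])
        _check_keys("stimulus", st, {"pulses", "file"})
        if "pulses" in st and "file" in st:
            raise ConfigError("stimulus: give either 'pulses' or 'file', not both")
        if "file" in st:
            path = (base_dir / st["file"]).resolve()
            if not path.exists():
                raise ConfigError(f"stimulus file does not exist: {path}")
            from .io import read_stimulus

            stimulus = read_stimulus(path)
        else:
            pulses = []
            for i, p in enumerate(st.get("pulses", [])):
                pd = dict(p)
                _check_keys(f"stimulus.pulses[{i}]", pd, {"t_start", "area", "width", "shape"})
                pulses.append(
                    Pulse(
                        t_start=float(pd["t_start"]),
                        area=float(pd["area"]),
                        width=float(pd["width"]),
                        shape=pd.get("shape", "rectangular"),
                    )
                )
            stimulus = StimulusProgram(tuple(pulses))

    design = None
    if data.get("design") is not None:
        de = dict(data["design"])
        _check_keys("design", de, {"sigma", "n_spikes", "set_times"})
        design = DesignSpec(
            sigma=float(de.get("sigma", 0.02)),
            n_spikes=int(de.get("n_spikes", 1)),
            set_times=tuple(float(v) for v in de.get("set_times", (0.0,))),
        )

    settings = IntegrationSettings()
    if data.get("settings") is not None:
        se = dict(data["settings"])
        _check_keys("settings", se, {"rtol", "atol", "max_step", "dt", "method"})
        settings = IntegrationSettings(
            rtol=float(se.get("rtol", settings.rtol)),
            atol=float(se.get("atol", settings.atol)),
            max_step=float(se.get("max_step", settings.max_step)),
            dt=float(se.get("dt", settings.dt)),
            method=str(se.get("method", settings.method)),
        )

    return RunConfig(
        params=params,
        scenario=scenario,
        stimulus=stimulus,
        design=design,
        settings=settings,
        seed=int(data.get("seed", 0)),
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level of a config must be a mapping")
    return _config_from_dict(data, path.parent)


def save_config(cfg: RunConfig, path) -> None:
    """Write a run configuration to YAML (with a version key)."""
    data: dict = {"version": CONFIG_VERSION, "params": dataclasses.asdict(cfg.params)}
    if cfg.scenario is not None:
        data["scenario"] = {
            "form": cfg.scenario.form,
            "initial": list(cfg.scenario.initial),
            "t_span": list(cfg.scenario.t_span),
        }
    if cfg.stimulus.pulses:
        data["stimulus"] = {
            "pulses": [
                {"t_start": p.t_start, "area": p.area, "width": p.width, "shape": p.shape}
                for p in cfg.stimulus.pulses
            ]
        }
    if cfg.design is not None:
        data["design"] = {
            "sigma": cfg.design.sigma,
            "n_spikes": cfg.design.n_spikes,
            "set_times": list(cfg.design.set_times),
        }
    data["settings"] = dataclasses.asdict(cfg.settings)
    data["seed"] = cfg.seed
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _spike_fixture(n_spikes: int, set_times: tuple[float, ...], t_end: float) -> RunConfig:
    design = design_spike(REFERENCE_PARAMS, sigma=0.02)
    stim = build_stimulus(design, n_spikes=n_spikes, spike_times=list(set_times))
    q0 = design.Q0_init
    return RunConfig(
        params=REFERENCE_PARAMS,
        scenario=Scenario(form="qcoords", initial=(q0, q0, 0.0), t_span=(0.0, t_end)),
        stimulus=stim,
        design=DesignSpec(sigma=0.02, n_spikes=n_spikes, set_times=set_times),
    )


def _fixture_reference() -> RunConfig:
    return RunConfig(params=REFERENCE_PARAMS)


def _fixture_pulse_to_equilibrium() -> RunConfig:
    return RunConfig(
        params=REFERENCE_PARAMS,
        scenario=Scenario(form="qcoords", initial=(-2.0, -2.0, 0.0), t_span=(0.0, 160.0)),
        stimulus=StimulusProgram((Pulse(t_start=10.0, area=0.5, width=1.0),)),
    )


def _fixture_pulse_to_oscillation() -> RunConfig:
    return RunConfig(
        params=REFERENCE_PARAMS,
        scenario=Scenario(form="qcoords", initial=(-2.0, -2.0, 0.0), t_span=(0.0, 120.0)),
        stimulus=StimulusProgram((Pulse(t_start=10.0, area=2.5, width=1.0),)),
    )


_FIXTURES = {
    "reference": _fixture_reference,
    "pulse-to-equilibrium": _fixture_pulse_to_equilibrium,
    "pulse-to-oscillation": _fixture_pulse_to_oscillation,
    "spike": lambda: _spike_fixture(1, (2.0,), 20.0),
    "burst": lambda: _spike_fixture(8, (10.0, 60.0, 110.0), 160.0),
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def fixture(name: str) -> RunConfig:
    """Return a named preset configuration from the fixture catalog."""
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}") from None
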