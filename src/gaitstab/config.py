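"""Run configuration: flat key-value files resolved into walker parameters.

A config file is a flat YAML mapping (no nesting except the perturbation
list), e.g.::

    leg_length: 1.0
    cadence: 120
    b_o: 0.02
    b_p: 2.5
    b_d: 0.6
    mode: alternating
    n_steps: 20
    perturbations:
      - [1.0, 0.01, 0.0]

Exactly one of ``omega``/``leg_length`` and exactly one of
``t_step``/``cadence`` must be given; the conversions ``omega =
sqrt(g/l)`` and ``t_step = 60/cadence`` are applied once at resolution.
Unknown keys are rejected by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ConfigError
from .synth import NoiseSpec
from .walker import PerturbationEvent, WalkerParams, eigenfrequency_from_leg_length

KNOWN_KEYS = {
    "omega",
    "leg_length",
    "b_o",
    "b_p",
    "b_d",
    "t_step",
    "cadence",
    "mode",
    "n_steps",
    "dt",
    "seed",
    "sigma_p",
    "sigma_sense_q",
    "sigma_sense_v",
    "perturbations",
    "out",
}

_DEFAULTS = {
    "b_o": 0.0,
    "b_p": 0.0,
    "b_d": 0.0,
    "mode": "progressive",
    "n_steps": 20,
    "dt": 0.005,
    "seed": 0,
    "sigma_p": 0.0,
    "sigma_sense_q": 0.0,
    "sigma_sense_v": 0.0,
}


@dataclass
class RunConfig:
    """Resolved run configuration (walker parameters plus run controls)."""

    params: WalkerParams
    n_steps: int = 20
    dt: float = 0.005
    seed: int = 0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    perturbations: list[PerturbationEvent] = field(default_factory=list)
    out: str | None = None

    def provenance(self) -> dict:
        """Flat key-value record of the resolved configuration."""
        p = self.params
        d = {
            "omega": p.omega,
            "b_o": p.b_o,
            "b_p": p.b_p,
            "b_d": p.b_d,
            "t_step": p.t_step,
            "mode": p.mode,
            "n_steps": self.n_steps,
            "dt": self.dt,
            "seed": self.seed,
            "sigma_p": self.noise.sigma_p,
        }
        if p.leg_length is not None:
            d["leg_length"] = p.leg_length
        return d


def resolve_config(raw: dict) -> RunConfig:
    """Validate a flat key-value mapping and resolve it into a RunConfig."""
    unknown = sorted(set(raw) - KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")
    merged = {**_DEFAULTS, **{k: v for k, v in raw.items() if v is not None}}

    has_omega = "omega" in merged
    has_leg = "leg_length" in merged
    if has_omega == has_leg:
        raise ConfigError("exactly one of 'omega' or 'leg_length' must be given")
    omega = (
        float(merged["omega"])
        if has_omega
        else eigenfrequency_from_leg_length(float(merged["leg_length"]))
    )

    has_tstep = "t_step" in merged
    has_cad = "cadence" in merged
    if has_tstep == has_cad:
        raise ConfigError("exactly one of 't_step' or 'cadence' must be given")
    if has_cad and float(merged["cadence"]) <= 0:
        raise ConfigError("cadence must be positive")
    t_step = (
        float(merged["t_step"]) if has_tstep else 60.0 / float(merged["cadence"])
    )

    try:
        params = WalkerParams(
            omega=omega,
            b_o=float(merged["b_o"]),
            b_p=float(merged["b_p"]),
            b_d=float(merged["b_d"]),
            t_step=t_step,
            mode=str(merged["mode"]),
            leg_length=float(merged["leg_length"]) if has_leg else None,
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from None

    perts = []
    for item in merged.get("perturbations", []) or []:
        if len(item) != 3:
            raise ConfigError(
                f"perturbation entries must be (time, dx, dv) triples, got {item!r}"
            )
        perts.append(PerturbationEvent(*map(float, item)))

    return RunConfig(
        params=params,
        n_steps=int(merged["n_steps"]),
        dt=float(merged["dt"]),
        seed=int(merged["seed"]),
        noise=NoiseSpec(
            sigma_p=float(merged["sigma_p"]),
            sigma_sense_q=float(merged["sigma_sense_q"]),
            sigma_sense_v=float(merged["sigma_sense_v"]),
            seed=int(merged["seed"]),
        ),
        perturbations=perts,
        out=merged.get("out"),
    )


def load_config(path) -> RunConfig:
    """Load and resolve a flat key-value YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must be a flat key-value mapping")
    return resolve_config(raw)
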