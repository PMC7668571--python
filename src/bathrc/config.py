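"""Flat key-value parameter files.

One dialect: a flat YAML mapping (``key: value`` per line).  Recognised keys:

===================  =============================================  ========
key                  meaning                                        default
===================  =============================================  ========
pinsp                inspiratory pressure above PEEP, cmH2O         required
peep                 positive end-expiratory pressure, cmH2O        required
rr                   respiratory rate, breaths/min                  required
ie_e                 expiratory part E of the I:E ratio 1:E         2.0
r_v                  tubing resistance, cmH2O/(L/s)                 required
c_v                  tubing compliance, L/cmH2O                     0.0
r_lung               patient airway resistance, cmH2O/(L/s)         required
c_lung               lung compliance, L/cmH2O                       required
r_restrictor_insp    added inspiratory restrictor, cmH2O/(L/s)      0.0
r_restrictor_exp     added expiratory restrictor, cmH2O/(L/s)       0.0
===================  =============================================  ========
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .exceptions import ConfigError
from .rc_core import CircuitParams, LungParams, VentSettings

__all__ = ["load_config", "write_config", "CONFIG_KEYS"]

_REQUIRED = ("pinsp", "peep", "rr", "r_v", "r_lung", "c_lung")
_DEFAULTS = {
    "ie_e": 2.0,
    "c_v": 0.0,
    "r_restrictor_insp": 0.0,
    "r_restrictor_exp": 0.0,
}
CONFIG_KEYS = _REQUIRED + tuple(_DEFAULTS)


def load_config(path) -> tuple[VentSettings, LungParams, CircuitParams]:
    """Read a parameter file and build the three parameter objects."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a flat key-value mapping")
    unknown = set(raw) - set(CONFIG_KEYS)
    if unknown:
        raise ConfigError(f"{path}: unknown keys: {', '.join(sorted(unknown))}")
    missing = [k for k in _REQUIRED if k not in raw]
    if missing:
        raise ConfigError(f"{path}: missing keys: {', '.join(missing)}")
    vals = dict(_DEFAULTS)
    vals.update(raw)
    for key, v in vals.items():
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ConfigError(f"{path}: {key} must be a number, got {v!r}")
    settings = VentSettings(
        pinsp=float(vals["pinsp"]),
        peep=float(vals["peep"]),
        rr=float(vals["rr"]),
        ie_e=float(vals["ie_e"]),
    )
    lung = LungParams(r=float(vals["r_lung"]), c=float(vals["c_lung"]))
    circuit = CircuitParams(
        r_v=float(vals["r_v"]),
        c_v=float(vals["c_v"]),
        r_restrictor_insp=float(vals["r_restrictor_insp"]),
        r_restrictor_exp=float(vals["r_restrictor_exp"]),
    )
    return settings, lung, circuit


def write_config(
    path,
    settings: VentSettings,
    lung: LungParams,
    circuit: CircuitParams,
) -> None:
    """Write the parameters back out in the same flat dialect."""
    vals = {
        "pinsp": settings.pinsp,
        "peep": settings.peep,
        "rr": settings.rr,
        "ie_e": settings.ie_e,
        "r_v": circuit.r_v,
        "c_v": circuit.c_v,
        "r_lung": lung.r,
        "c_lung": lung.c,
        "r_restrictor_insp": circuit.r_restrictor_insp,
        "r_restrictor_exp": circuit.r_restrictor_exp,
    }
    lines = [f"{k}: {v}" for k, v in vals.items()]
    Path(path).write_text("\n".join(lines) + "\n")
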