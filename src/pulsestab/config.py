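"""Network configuration and the flat key:value config-file format."""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

from .fields import VelocityField, field_catalog
from .pulses import PulseModel

__all__ = ["NetworkConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class NetworkConfig:
    """A globally coupled network of N identical pulse-coupled neurons.

    g is the (signed) coupling constant — negative means inhibitory.
    A and T_a describe an optional common periodic drive A cos(2 pi t / T_a);
    A = 0 is the autonomous network.
    """

    N: int
    g: float
    field: VelocityField
    pulse: PulseModel
    forcing_A: float = 0.0
    forcing_Ta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("need at least N = 2 neurons")
        if self.forcing_A != 0.0 and (self.forcing_Ta is None or self.forcing_Ta <= 0):
            raise ValueError("forced networks need a positive forcing period T_a")

    @property
    def omega(self) -> float:
        if self.forcing_Ta is None:
            return 0.0
        return 2.0 * math.pi / self.forcing_Ta

    @property
    def resolved_pulse(self) -> PulseModel:
        """Pulse with any N-scaled rate bound to this network's size."""
        return self.pulse.resolve(self.N)

    def with_N(self, N: int) -> "NetworkConfig":
        return replace(self, N=N)


_KNOWN_KEYS = {
    "field", "a", "pulse", "alpha", "beta", "poles", "N", "g",
    "A", "T_a", "seed", "dt_factor", "n_spikes",
}


def _parse_pulse(kind: str, items: dict) -> PulseModel:
    kind = kind.lower()
    if kind == "delta":
        return PulseModel.delta()
    if kind == "exp":
        return PulseModel.exponential(float(items["alpha"]))
    if kind == "alpha":
        return PulseModel.alpha_pulse(float(items["alpha"]))
    if kind == "beta":
        return PulseModel.beta_pulse(float(items["beta"]))
    if kind == "general":
        poles = [float(p) for p in str(items["poles"]).split(",")]
        return PulseModel.general(poles)
    raise ValueError(f"unknown pulse kind {kind!r} (delta|exp|alpha|beta|general)")


def load_config(path) -> NetworkConfig:
    """Read a flat ``key: value`` (or ``key = value``) configuration file.

    Unknown keys are an error; ``#`` starts a comment.
    """
    items: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in (":", "="):
            if sep in line:
                key, val = line.split(sep, 1)
                break
        else:
            raise ValueError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
        key = key.strip()
        if key not in _KNOWN_KEYS:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        items[key] = val.strip()

    field = field_catalog(items.get("field", "F0"), float(items.get("a", 1.3)))
    pulse = _parse_pulse(items.get("pulse", "alpha"), items)
    return NetworkConfig(
        N=int(items.get("N", 100)),
        g=float(items.get("g", -0.4)),
        field=field,
        pulse=pulse,
        forcing_A=float(items.get("A", 0.0)),
        forcing_Ta=float(items["T_a"]) if "T_a" in items else None,
    )


def dump_config(cfg: NetworkConfig) -> dict:
    """JSON-serializable echo of a configuration (for output sidecars)."""
    p = cfg.pulse
    if p.is_delta:
        pulse = {"kind": "delta"}
    elif p.scaled_with_N:
        pulse = {"kind": "beta", "beta": p.beta}
    elif p.order_L == 1:
        pulse = {"kind": "exp", "alpha": p.poles[0]}
    elif p.order_L == 2 and p.poles[0] == p.poles[1]:
        pulse = {"kind": "alpha", "alpha": p.poles[0]}
    else:
        pulse = {"kind": "general", "poles": list(p.poles)}
    out = {
        "field": cfg.field.name, "a": cfg.field.param_a,
        "continuity_class": cfg.field.continuity_class,
        "pulse": pulse, "N": cfg.N, "g": cfg.g,
        "A": cfg.forcing_A,
    }
    if cfg.forcing_Ta is not None:
        out["T_a"] = cfg.forcing_Ta
    return out
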