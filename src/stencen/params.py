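"""Model parameters for the coupled STEN-CEN excitable system.

The model couples two activator-inhibitor (FitzHugh-Nagumo-like) excitable
networks: a slow signal-transduction network (STEN, fields ``F_S``/``R_S``)
that organizes propagating cortical waves, and a fast cytoskeletal network
(CEN, fields ``F_C``/``R_C``) slaved to STEN through the coupling drive
``s_in = s_c * (R_S - r0)``.  CEN feeds back onto STEN's stochastic drive
through a fast local positive species ``Z_C`` and a slow, effectively global
negative species ``W_C``: the STEN noise amplitude is
``sigma_N = u_b + Z_C - W_C`` (clamped at zero).

All quantities are nondimensional.  An optional calibration pair
(seconds per time unit, microns per grid step) may be attached to readouts
as metadata; the dynamics never use it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Union


class ConfigError(ValueError):
    """Raised for malformed or unknown-key parameter configs."""


@dataclass
class STENParams:
    """Signal-transduction excitable network (slow module).

    Activator rate: ``-(a1s + a2s*R)*F + a3s*F^2/(a4s^2 + F^2) + a5s + u_n``.
    Inhibitor rate: ``eps_s * (-R + c1s*F)``.

    ``a3s`` sets the strength of the autocatalytic positive feedback (shape
    of the cubic activator nullcline); ``c1s`` the slope of the inhibitor
    nullcline (and hence the resting inhibition level ``r0``); ``eps_s`` the
    slowness of the inhibitor; ``u_b`` the basal stochastic drive present
    even when the cytoskeleton is silenced.
    """

    d_fs: float = 1.0
    d_rs: float = 3.0
    a1s: float = 1.0
    a2s: float = 2.0
    a3s: float = 10.0
    a4s: float = 1.0
    a5s: float = 0.1
    eps_s: float = 0.03
    c1s: float = 10.0
    u_b: float = 0.3
    r0: float = 0.6173865225325263

    # names used by the generic nullcline algebra
    @property
    def a1(self) -> float:
        return self.a1s

    @property
    def a2(self) -> float:
        return self.a2s

    @property
    def a3(self) -> float:
        return self.a3s

    @property
    def a4(self) -> float:
        return self.a4s

    @property
    def a5(self) -> float:
        return self.a5s

    @property
    def eps(self) -> float:
        return self.eps_s

    @property
    def c1(self) -> float:
        return self.c1s

    def validate(self) -> None:
        for name in ("d_fs", "d_rs", "a1s", "a2s", "a3s", "a4s", "a5s",
                     "eps_s", "c1s", "u_b", "r0"):
            v = getattr(self, name)
            if not (v >= 0):
                raise ConfigError(f"STEN parameter {name} must be >= 0, got {v}")
        if self.eps_s <= 0:
            raise ConfigError("eps_s must be > 0")
        if self.a4s <= 0:
            raise ConfigError("a4s must be > 0")


@dataclass
class CENParams:
    """Cytoskeletal excitable network (fast module).

    Same functional form as STEN except that the STEN coupling ``s_in``
    offsets the effective inhibition, ``-(a1c + a2c*(R - s_in))*F + ...``,
    which raises the activator nullcline and lowers the firing threshold.
    ``eps_c`` is eight-fold larger than ``eps_s`` by default, so CEN firings
    are brief and spatially confined (puncta) rather than propagating.
    ``sigma_c`` is the amplitude of CEN's own stochastic drive.
    """

    d_fc: float = 0.3
    d_rc: float = 0.5
    a1c: float = 1.0
    a2c: float = 2.0
    a3c: float = 10.0
    a4c: float = 1.0
    a5c: float = 0.1
    eps_c: float = 0.24
    c1c: float = 10.0
    s_c: float = 1.0
    sigma_c: float = 0.55

    @property
    def a1(self) -> float:
        return self.a1c

    @property
    def a2(self) -> float:
        return self.a2c

    @property
    def a3(self) -> float:
        return self.a3c

    @property
    def a4(self) -> float:
        return self.a4c

    @property
    def a5(self) -> float:
        return self.a5c

    @property
    def eps(self) -> float:
        return self.eps_c

    @property
    def c1(self) -> float:
        return self.c1c

    def validate(self) -> None:
        for name in ("d_fc", "d_rc", "a1c", "a2c", "a3c", "a4c", "a5c",
                     "eps_c", "c1c", "s_c", "sigma_c"):
            v = getattr(self, name)
            if not (v >= 0):
                raise ConfigError(f"CEN parameter {name} must be >= 0, got {v}")
        if self.eps_c <= 0:
            raise ConfigError("eps_c must be > 0")
        if self.a4c <= 0:
            raise ConfigError("a4c must be > 0")


@dataclass
class FeedbackParams:
    """CEN-to-STEN feedback species.

    ``dZ/dt = -p1*Z + p2*F_C`` (fast, local positive feedback) and
    ``dW/dt = -p3*W + p4*F_C`` (slow, global negative feedback; ``d_wc`` is
    large enough that W_C is spatially near-uniform).  The steady-state
    negative gain ``p4/p3`` is twice the positive gain ``p2/p1`` in the
    defaults.
    """

    d_zc: float = 0.3
    d_wc: float = 500.0
    p1: float = 0.5
    p2: float = 0.1
    p3: float = 0.05
    p4: float = 0.02

    def validate(self) -> None:
        for name in ("d_zc", "d_wc", "p1", "p2", "p3", "p4"):
            v = getattr(self, name)
            if not (v >= 0):
                raise ConfigError(f"feedback parameter {name} must be >= 0, got {v}")


ExcitableParams = Union[STENParams, CENParams]


@dataclass
class ModelParams:
    """Full parameter set of the five coupled reaction-diffusion pairs."""

    sten: STENParams = field(default_factory=STENParams)
    cen: CENParams = field(default_factory=CENParams)
    feedback: FeedbackParams = field(default_factory=FeedbackParams)

    def validate(self) -> None:
        self.sten.validate()
        self.cen.validate()
        self.feedback.validate()

    def copy(self) -> "ModelParams":
        return ModelParams(
            sten=dataclasses.replace(self.sten),
            cen=dataclasses.replace(self.cen),
            feedback=dataclasses.replace(self.feedback),
        )

    # -- flat parameter-path access, used by perturbation ramps ------------

    def get(self, path: str) -> float:
        group, name = self._split(path)
        return getattr(group, name)

    def set(self, path: str, value: float) -> None:
        group, name = self._split(path)
        setattr(group, name, float(value))

    def _split(self, path: str):
        for group in (self.sten, self.cen, self.feedback):
            if path in _group_fields(group):
                return group, path
        raise KeyError(f"unknown parameter path: {path!r}")

    # -- flat structured-text config ---------------------------------------

    def to_config_text(self) -> str:
        lines = []
        for group in (self.sten, self.cen, self.feedback):
            for name in _group_fields(group):
                lines.append(f"{name} = {getattr(group, name)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config_text(cls, text: str) -> "ModelParams":
        p = cls()
        known = set()
        for group in (p.sten, p.cen, p.feedback):
            known |= set(_group_fields(group))
        seen = set()
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ConfigError(f"line {lineno}: unknown parameter {key!r}")
            if key in seen:
                raise ConfigError(f"line {lineno}: duplicate parameter {key!r}")
            seen.add(key)
            try:
                p.set(key, float(val.strip()))
            except ValueError as exc:
                raise ConfigError(f"line {lineno}: bad value for {key!r}") from exc
        p.validate()
        return p


def _group_fields(group) -> tuple:
    return tuple(f.name for f in dataclasses.fields(group))


def default_params() -> ModelParams:
    """The shipped default parameter set (excitable STEN, 8x faster CEN)."""
    return ModelParams()
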