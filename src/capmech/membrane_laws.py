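"""Membrane constitutive laws for thin hyper-elastic capsule membranes.

Three classical two-dimensional laws are supported:

* **neo-Hookean (NH)** — strain-softening, volume-incompressible rubber-like
  membrane; area dilatation is compensated by thinning, so the area-dilatation
  modulus is fixed at ``Ks = 3 Gs``.
* **Skalak (SK)** — strain-hardening law for red-blood-cell-like membranes,
  with dimensionless area-dilatation parameter ``C``; ``Ks = (1 + 2C) Gs``.
* **2D Hooke** — linear elasticity with surface Poisson ratio ``nu_s``;
  ``Ks = (1 + nu_s) / (1 - nu_s) Gs``.

Strain states are expressed through the two surface strain invariants, using
the shifted convention ``I1 = lam1^2 + lam2^2 - 2`` and
``I2 = lam1^2 lam2^2 - 1`` so that the undeformed membrane sits at
``(I1, I2) = (0, 0)`` with zero strain energy for every law.

The module also handles the dimensionless flow groups: the capillary numbers
``Ca^Gs = mu U / Gs`` and ``Ca^Ks = mu U / Ks`` that compare the viscous fluid
stress with the membrane shear and area-dilatation resistances, the
confinement ratio ``beta = a / R`` and the osmotic pre-inflation ratio
``alpha = a / a0 - 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Tuple, Union

__all__ = [
    "LawKind",
    "LawParameters",
    "SurfaceStrainState",
    "FlowCondition",
    "strain_energy",
    "area_dilatation_modulus",
    "equivalent_parameters",
    "capillary_numbers",
    "moduli_from_capillary",
]


class LawKind(str, Enum):
    """Membrane constitutive-law family."""

    NEO_HOOKEAN = "neo_hookean"
    SKALAK = "skalak"
    HOOKE = "hooke"

    @classmethod
    def coerce(cls, value: Union["LawKind", str]) -> "LawKind":
        if isinstance(value, cls):
            return value
        key = str(value).strip().lower()
        aliases = {
            "nh": cls.NEO_HOOKEAN,
            "neo-hookean": cls.NEO_HOOKEAN,
            "neohookean": cls.NEO_HOOKEAN,
            "sk": cls.SKALAK,
            "skalak": cls.SKALAK,
            "hooke": cls.HOOKE,
            "hookes": cls.HOOKE,
            "h": cls.HOOKE,
        }
        if key in aliases:
            return aliases[key]
        return cls(key)


# Canonical class ordering used by the classifier head and confusion tables.
LAW_ORDER: Tuple[LawKind, ...] = (LawKind.NEO_HOOKEAN, LawKind.SKALAK, LawKind.HOOKE)


@dataclass(frozen=True)
class LawParameters:
    """A constitutive law together with its elastic parameters.

    ``Gs`` is the membrane shear modulus (N/m). ``C`` (Skalak) and ``nu_s``
    (Hooke) are the law-specific dimensionless parameters; the area-dilatation
    modulus ``Ks`` is always *derived* from them, never stored.
    """

    kind: LawKind
    Gs: float = 1.0
    C: Optional[float] = None
    nu_s: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", LawKind.coerce(self.kind))
        if not self.Gs > 0:
            raise ValueError(f"Gs must be positive, got {self.Gs}")
        if self.kind is LawKind.SKALAK:
            if self.C is None:
                raise ValueError("Skalak law requires the area-dilatation parameter C")
            if not self.C > 0:
                raise ValueError(f"Skalak C must be positive, got {self.C}")
        if self.kind is LawKind.HOOKE:
            if self.nu_s is None:
                raise ValueError("Hooke law requires the surface Poisson ratio nu_s")
            if not 0.0 < self.nu_s < 1.0:
                raise ValueError(f"nu_s must lie in (0, 1), got {self.nu_s}")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        out = {"kind": self.kind.value, "Gs": self.Gs}
        if self.C is not None:
            out["C"] = self.C
        if self.nu_s is not None:
            out["nu_s"] = self.nu_s
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "LawParameters":
        return cls(
            kind=LawKind.coerce(data["kind"]),
            Gs=float(data.get("Gs", 1.0)),
            C=None if data.get("C") is None else float(data["C"]),
            nu_s=None if data.get("nu_s") is None else float(data["nu_s"]),
        )

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "LawParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class SurfaceStrainState:
    """Surface strain invariants (shifted so the rest state is (0, 0))."""

    I1: float
    I2: float

    def __post_init__(self) -> None:
        if self.I2 < -1.0:
            raise ValueError(f"I2 = {self.I2} violates I2 >= -1 (vanishing area)")

    @classmethod
    def from_stretches(cls, lam1: float, lam2: float) -> "SurfaceStrainState":
        return cls(I1=lam1**2 + lam2**2 - 2.0, I2=(lam1 * lam2) ** 2 - 1.0)


@dataclass(frozen=True)
class FlowCondition:
    """Tube-flow operating point.

    mu: suspending-fluid dynamic viscosity (Pa s); U: capsule/mean flow speed
    (m/s); R: tube radius (m); a0: unstressed capsule radius (m); alpha:
    osmotic pre-inflation ratio (inflated radius a = (1 + alpha) a0).
    """

    mu: float
    U: float
    R: float = 1.0
    a0: float = 0.77
    alpha: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mu", "U", "R", "a0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if not 0.0 < self.beta < 1.0:
            raise ValueError(
                f"inflated capsule radius a = {self.a} must be smaller than the tube radius"
            )

    @property
    def a(self) -> float:
        """Inflated capsule radius."""
        return (1.0 + self.alpha) * self.a0

    @property
    def beta(self) -> float:
        """Confinement ratio a / R."""
        return self.a / self.R


def strain_energy(
    law: LawParameters, state: SurfaceStrainState, as_printed: bool = False
) -> float:
    """Strain energy density W (units of Gs per unit undeformed area).

    ``as_printed`` switches the neo-Hookean incompressibility term to the
    literal ``1/(I2 - 1)`` form, which is singular at the rest state under the
    shifted-invariant convention; the default ``1/(I2 + 1)`` is the standard
    2D NH energy with W(rest) = 0.
    """
    I1, I2 = state.I1, state.I2
    Gs = law.Gs
    if law.kind is LawKind.NEO_HOOKEAN:
        denom = (I2 - 1.0) if as_printed else (I2 + 1.0)
        if denom == 0.0:
            raise ZeroDivisionError("NH energy singular: vanishing I2 denominator")
        return 0.5 * Gs * (I1 - 1.0 + 1.0 / denom)
    if law.kind is LawKind.SKALAK:
        return 0.25 * Gs * (I1**2 + 2.0 * I1 - 2.0 * I2) + 0.25 * law.C * Gs * I2**2
    if law.kind is LawKind.HOOKE:
        return 0.25 * Gs * (2.0 * I1 - 2.0 * I2 + I1**2 / (1.0 - law.nu_s))
    raise ValueError(f"unknown law kind {law.kind!r}")  # pragma: no cover


def area_dilatation_modulus(law: LawParameters) -> float:
    """Area-dilatation modulus Ks implied by the law.

    NH: Ks = 3 Gs; SK: Ks = (1 + 2C) Gs; Hooke: Ks = (1 + nu_s)/(1 - nu_s) Gs.
    """
    if law.kind is LawKind.NEO_HOOKEAN:
        return 3.0 * law.Gs
    if law.kind is LawKind.SKALAK:
        return (1.0 + 2.0 * law.C) * law.Gs
    if law.kind is LawKind.HOOKE:
        return (1.0 + law.nu_s) / (1.0 - law.nu_s) * law.Gs
    raise ValueError(f"unknown law kind {law.kind!r}")  # pragma: no cover


def equivalent_parameters(ks_over_gs: float) -> Tuple[float, float]:
    """Skalak ``C`` and Hooke ``nu_s`` matching a given Ks/Gs ratio.

    Inverts the two Ks relations at equal modulus ratio:
    ``C = (r - 1) / 2`` and ``nu_s = (r - 1) / (r + 1)``.
    """
    r = float(ks_over_gs)
    if r < 1.0:
        raise ValueError(
            f"Ks/Gs = {r} < 1 would require negative C or nu_s; membranes in scope "
            "resist area dilatation at least as much as shear"
        )
    return (r - 1.0) / 2.0, (r - 1.0) / (r + 1.0)


def capillary_numbers(flow: FlowCondition, law: LawParameters) -> Tuple[float, float]:
    """(Ca^Gs, Ca^Ks) = (mu U / Gs, mu U / Ks) for a law at a flow condition."""
    ks = area_dilatation_modulus(law)
    return flow.mu * flow.U / law.Gs, flow.mu * flow.U / ks


def moduli_from_capillary(
    flow: FlowCondition, ca_gs: float, ca_ks: float
) -> Tuple[float, float]:
    """(Gs, Ks) recovered from the capillary numbers: Gs = mu U / Ca^Gs etc."""
    if not (ca_gs > 0 and ca_ks > 0):
        raise ValueError("capillary numbers must be positive")
    return flow.mu * flow.U / ca_gs, flow.mu * flow.U / ca_ks
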