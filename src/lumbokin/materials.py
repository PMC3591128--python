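"""Constitutive laws for the lumbar motion-segment model.

The material set comprises four families:

* **bilinear tension-only ligaments** — linear with modulus ``E1`` up to a
  transition strain, then ``E2``; zero stress in compression;
* **tension-only annulus fibre layers** — linear, with moduli increasing
  from the innermost to the outermost sheet;
* **a Mooney-Rivlin incompressible nucleus pulposus** (healthy) or a
  compressible elastic nucleus (degenerated / elastic-comparison variant);
* **elastic annulus ground substance and facet cartilage**.

Material cards are shipped as YAML package data and schema-checked on load.
All moduli are MPa, strains dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "BilinearLaw",
    "MooneyRivlinNucleus",
    "ElasticNucleus",
    "MaterialCard",
    "uniaxial_stress",
    "fiber_stress",
    "mooney_rivlin_uniaxial",
    "load_card",
    "elastic_comparison_card",
    "LIGAMENT_NAMES",
]

LIGAMENT_NAMES = ("ALL", "PLL", "LF", "ITL", "CL", "ISL", "SSL", "ILL")


@dataclass(frozen=True)
class BilinearLaw:
    """Bilinear tension-only uniaxial law (MPa, strain as a fraction)."""

    E1: float
    transition_strain: float
    E2: float
    tension_only: bool = True

    def __post_init__(self) -> None:
        if self.E1 <= 0 or self.E2 <= 0:
            raise ValueError("bilinear law moduli must be positive")
        if not 0.0 < self.transition_strain < 1.0:
            raise ValueError("transition strain must lie in (0, 1)")


@dataclass(frozen=True)
class MooneyRivlinNucleus:
    """Incompressible Mooney-Rivlin nucleus pulposus."""

    C01: float = 0.0343
    C10: float = 0.1369
    incompressible: bool = True

    def __post_init__(self) -> None:
        if self.C01 <= 0 or self.C10 <= 0:
            raise ValueError("Mooney-Rivlin constants must be positive")

    @property
    def shear_modulus(self) -> float:
        """Small-strain shear modulus mu = 2 (C10 + C01), MPa."""
        return 2.0 * (self.C10 + self.C01)


@dataclass(frozen=True)
class ElasticNucleus:
    """Compressible linear-elastic nucleus (degenerated or comparison)."""

    E: float
    nu: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("nucleus modulus must be positive")
        if not -1.0 < self.nu < 0.5:
            raise ValueError("nucleus Poisson ratio must lie in (-1, 0.5)")

    @property
    def shear_modulus(self) -> float:
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def bulk_modulus(self) -> float:
        return self.E / (3.0 * (1.0 - 2.0 * self.nu))


@dataclass(frozen=True)
class Elastic:
    E: float
    nu: float


@dataclass(frozen=True)
class MaterialCard:
    """One complete material transcription (healthy or degenerated)."""

    name: str
    annulus: Elastic
    nucleus: MooneyRivlinNucleus | ElasticNucleus
    fiber_layer_E: tuple[float, ...]
    ligaments: Mapping[str, BilinearLaw]
    cartilage: Elastic
    bone: Mapping[str, Elastic] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.fiber_layer_E) != 5:
            raise ValueError("exactly five fibre layers expected")
        if any(e <= 0 for e in self.fiber_layer_E):
            raise ValueError("fibre moduli must be positive")
        if np.any(np.diff(self.fiber_layer_E) <= 0):
            raise ValueError("fibre moduli must increase strictly with layer index")
        missing = set(LIGAMENT_NAMES) - set(self.ligaments)
        if missing:
            raise ValueError(f"material card missing ligaments: {sorted(missing)}")
        if self.annulus.E <= 0:
            raise ValueError("annulus modulus must be positive")


def uniaxial_stress(law: BilinearLaw, strain) -> np.ndarray | float:
    """Bilinear tension-only stress (MPa).

    Zero for nonpositive strain, ``E1*eps`` up to the transition strain and
    ``E1*eps_t + E2*(eps - eps_t)`` beyond; continuous and nondecreasing.
    """
    eps = np.asarray(strain, dtype=float)
    eps_t = law.transition_strain
    low = law.E1 * np.clip(eps, 0.0, eps_t)
    high = law.E2 * np.clip(eps - eps_t, 0.0, None)
    out = low + high
    return float(out) if np.isscalar(strain) else out


def fiber_stress(layer_index: int, strain, card: MaterialCard) -> np.ndarray | float:
    """Tension-only linear fibre stress (MPa) for layer 1 (inner) .. 5 (outer)."""
    if not 1 <= int(layer_index) <= 5:
        raise ValueError(f"fibre layer index must be 1..5, got {layer_index}")
    E = card.fiber_layer_E[int(layer_index) - 1]
    eps = np.asarray(strain, dtype=float)
    out = E * np.clip(eps, 0.0, None)
    return float(out) if np.isscalar(strain) else out


def mooney_rivlin_uniaxial(nucleus: MooneyRivlinNucleus, stretch) -> np.ndarray | float:
    """Incompressible Mooney-Rivlin uniaxial Cauchy stress (MPa).

    sigma(lambda) = 2 (C10 + C01 / lambda) (lambda^2 - 1/lambda); zero at the
    identity deformation and monotone increasing around it.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    out = 2.0 * (nucleus.C10 + nucleus.C01 / lam) * (lam**2 - 1.0 / lam)
    return float(out) if np.isscalar(stretch) else out


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("lumbokin").joinpath("data", filename)))


def _parse_nucleus(raw: Mapping) -> MooneyRivlinNucleus | ElasticNucleus:
    model = raw.get("model", "elastic")
    if model == "mooney_rivlin":
        return MooneyRivlinNucleus(
            C01=float(raw["C01"]),
            C10=float(raw["C10"]),
            incompressible=bool(raw.get("incompressible", True)),
        )
    if model == "elastic":
        return ElasticNucleus(E=float(raw["E"]), nu=float(raw["nu"]))
    raise ValueError(f"unknown nucleus model {model!r}")


def load_card(source: str = "healthy", file: str | Path | None = None) -> MaterialCard:
    """Load a material card from package data or an explicit YAML file.

    ``source`` is ``"healthy"`` or ``"degenerated"``.  The degenerated card
    lists only the disc constituents; everything else (ligaments, cartilage,
    bone metadata) is inherited from the healthy card.
    """
    if source not in ("healthy", "degenerated"):
        raise ValueError("source must be 'healthy' or 'degenerated'")
    path = Path(file) if file is not None else _data_path(f"material_card_{source}.yaml")
    raw = yaml.safe_load(path.read_text())
    if source == "degenerated":
        base = yaml.safe_load(_data_path("material_card_healthy.yaml").read_text())
        base.update(raw)
        raw = base
    try:
        ligaments = {
            name: BilinearLaw(
                E1=float(v["E1"]),
                transition_strain=float(v["transition_strain"]),
                E2=float(v["E2"]),
            )
            for name, v in raw["ligaments"].items()
        }
        card = MaterialCard(
            name=str(raw.get("name", source)),
            annulus=Elastic(float(raw["annulus"]["E"]), float(raw["annulus"]["nu"])),
            nucleus=_parse_nucleus(raw["nucleus"]),
            fiber_layer_E=tuple(float(e) for e in raw["fiber_layers"]["E"]),
            ligaments=ligaments,
            cartilage=Elastic(float(raw["cartilage"]["E"]), float(raw["cartilage"]["nu"])),
            bone={k: Elastic(float(v["E"]), float(v["nu"])) for k, v in raw.get("bone", {}).items()},
        )
    except KeyError as exc:  # pragma: no cover - message content only
        raise ValueError(f"material card {path} is missing field {exc}") from exc
    return card


def elastic_comparison_card(E: float = 1.0, nu: float = 0.49) -> MaterialCard:
    """Healthy card with the nucleus replaced by the compressible elastic
    comparison material (default E = 1.0 MPa, nu = 0.49)."""
    card = load_card("healthy")
    return MaterialCard(
        name="healthy-elastic-nucleus",
        annulus=card.annulus,
        nucleus=ElasticNucleus(E=E, nu=nu),
        fiber_layer_E=card.fiber_layer_E,
        ligaments=card.ligaments,
        cartilage=card.cartilage,
        bone=card.bone,
    )
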