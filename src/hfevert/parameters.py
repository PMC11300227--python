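"""Material parameters of the elastic–viscoplastic–damage bone model.

The parameter set combines a Maxwell–Wiechert viscoelastic network (an
equilibrium spring ``E00`` in parallel with two spring–dashpot branches
``E01/eta01`` and ``E02/eta02``), a power-law viscoplastic flow rule
(reference stress ``S0``, rate exponent ``m``), a halfspacewise Hill
strength surface (``sigma0_minus/plus``, ``tau0``, interaction
coefficients ``chi0_minus/plus``) and a plasticity-coupled scalar damage
law (yield-to-ultimate ratio ``alpha``, hardening exponent ``k_hard``,
damage rate constant ``zeta``).

Moduli are given in GPa at the user boundary and converted to the
internal mm–N–s–MPa unit system exactly once (`MaterialParameters.mpa`).
Viscosities: ``eta01`` in MPa·s, ``eta02`` in kPa·s, as conventionally
tabulated for cortical bone.
"""

from __future__ import annotations

import dataclasses
import pathlib
import tomllib
from dataclasses import dataclass

import yaml


@dataclass(frozen=True)
class MaterialParameters:
    """Full constitutive parameter set.

    All moduli (``E00``, ``E01``, ``E02``, ``Emax``) in GPa; ``eta01`` in
    MPa·s; ``eta02`` in kPa·s; strengths (``S0``, ``sigma0_minus``,
    ``sigma0_plus``, ``tau0``) in MPa; everything else dimensionless.
    """

    E00: float = 2.9
    E01: float = 0.78
    E02: float = 4.18
    eta01: float = 0.24
    eta02: float = 0.40
    nu: float = 0.3
    S0: float = 140.0
    m: float = 18.24
    sigma0_minus: float = 140.0
    sigma0_plus: float = 86.8
    tau0: float = 49.0
    chi0_minus: float = 0.5
    chi0_plus: float = 0.5
    alpha: float = 0.78
    k_hard: float = 2.0
    k_exp: float = 2.0
    Emax: float = 10.0
    zeta: float = 10.0
    eta_D: float = 0.0

    def __post_init__(self) -> None:
        for name in ("E00", "E01", "E02", "eta01", "eta02", "S0",
                     "sigma0_minus", "sigma0_plus", "tau0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not (-1.0 < self.nu < 0.5):
            raise ValueError(f"nu must lie in (-1, 0.5), got {self.nu}")
        if self.m < 1:
            raise ValueError(f"rate exponent m must be >= 1, got {self.m}")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.k_exp <= 0:
            raise ValueError(f"k_exp must be positive, got {self.k_exp}")
        if self.Emax < self.E00:
            raise ValueError("Emax must be >= E00")

    # ------------------------------------------------------------------
    # unit conversion (applied once at the boundary)
    # ------------------------------------------------------------------
    def mpa(self) -> "MaterialParametersMPa":
        """Internal-unit view: moduli in MPa, viscosities in MPa·s."""
        return MaterialParametersMPa(
            E00=self.E00 * 1e3,
            E01=self.E01 * 1e3,
            E02=self.E02 * 1e3,
            eta01=self.eta01,
            eta02=self.eta02 * 1e-3,
            nu=self.nu,
            S0=self.S0,
            m=self.m,
            sigma0_minus=self.sigma0_minus,
            sigma0_plus=self.sigma0_plus,
            tau0=self.tau0,
            chi0_minus=self.chi0_minus,
            chi0_plus=self.chi0_plus,
            alpha=self.alpha,
            k_hard=self.k_hard,
            k_exp=self.k_exp,
            Emax=self.Emax * 1e3,
            zeta=self.zeta,
            eta_D=self.eta_D,
        )

    def replace(self, **changes) -> "MaterialParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    # ------------------------------------------------------------------
    # file I/O: flat key-value TOML (read) and YAML (read/write)
    # ------------------------------------------------------------------
    @classmethod
    def from_file(cls, path: str | pathlib.Path) -> "MaterialParameters":
        path = pathlib.Path(path)
        if path.suffix.lower() == ".toml":
            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | pathlib.Path) -> None:
        path = pathlib.Path(path)
        d = self.to_dict()
        if path.suffix.lower() == ".toml":
            lines = [f"{k} = {v!r}" for k, v in d.items()]
            path.write_text("\n".join(lines) + "\n")
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass(frozen=True)
class MaterialParametersMPa:
    """Parameter set in the internal mm–N–s–MPa system (do not construct
    directly; use :meth:`MaterialParameters.mpa`)."""

    E00: float
    E01: float
    E02: float
    eta01: float
    eta02: float
    nu: float
    S0: float
    m: float
    sigma0_minus: float
    sigma0_plus: float
    tau0: float
    chi0_minus: float
    chi0_plus: float
    alpha: float
    k_hard: float
    k_exp: float
    Emax: float
    zeta: float
    eta_D: float


def default_parameters() -> MaterialParameters:
    """Reference cortical-bone parameter table (packaged default)."""
    here = pathlib.Path(__file__).parent / "data" / "default_params.toml"
    return MaterialParameters.from_file(here)
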