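"""Isotropic linear-elastic material sets for head-model regions.

Unit system: mm / ton / s, hence stresses and moduli in MPa, densities in
ton/mm³ (1 g/cm³ = 1e-9 ton/mm³).  With these units the generalized
eigenproblem yields ω² directly in s⁻², so f = ω/2π is in Hz with no
conversion factor.

The named constructors reproduce the parameter combinations used in the
published multi-compartment head simulations: the Tse-style reference set
for boundary-condition comparisons, the heterogeneous/homogeneous pair for
the model-complexity comparison, and the CSF-stiffness sweep grid under
high- and low-stiffness brain-tissue scenarios.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, replace

__all__ = ["Material", "MaterialSet", "CSF_E_GRID", "BRAIN_STIFFNESS"]

#: CSF Young's modulus sweep grid (MPa), stiffest first (reference value)
CSF_E_GRID = (2.19, 1.314, 0.299, 0.1485, 0.012, 0.001)

#: (E_GM, E_WM) in MPa for the two brain-tissue stiffness scenarios
BRAIN_STIFFNESS = {"high": (0.01537, 0.03103), "low": (0.001389, 0.001895)}


@dataclass(frozen=True)
class Material:
    """Isotropic elastic constants: E in MPa, rho in ton/mm³, nu unitless."""

    E: float
    rho: float
    nu: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError(f"Young's modulus must be positive, got {self.E}")
        if self.rho <= 0:
            raise ValueError(f"density must be positive, got {self.rho}")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError(
                f"Poisson's ratio must satisfy 0 <= nu < 0.5, got {self.nu}")

    @property
    def lame_lambda(self) -> float:
        return self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))

    @property
    def lame_mu(self) -> float:
        return self.E / (2 * (1 + self.nu))


class MaterialSet(Mapping):
    """Mapping from region label to :class:`Material`."""

    def __init__(self, materials: Mapping[str, Material]):
        self._materials = dict(materials)

    def __getitem__(self, key: str) -> Material:
        return self._materials[key]

    def __iter__(self):
        return iter(self._materials)

    def __len__(self) -> int:
        return len(self._materials)

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}={v}" for k, v in self._materials.items())
        return f"MaterialSet({inner})"

    def scaled(self, c: float) -> "MaterialSet":
        """All Young's moduli multiplied by ``c`` (ν, ρ unchanged).

        Scales the global stiffness matrix exactly by ``c``, so every
        eigenvalue scales by ``c`` and eigenvectors are unchanged.
        """
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return MaterialSet(
            {k: replace(m, E=c * m.E) for k, m in self._materials.items()})

    def with_nu_cap(self, nu_max: float | None) -> "MaterialSet":
        """Cap Poisson's ratios at ``nu_max`` (volumetric-locking guard).

        Low-order displacement tetrahedra lock as ν → 0.5; capping the
        near-incompressible CSF value keeps eigenfrequencies trustworthy.
        ``None`` returns the set unchanged (faithful mode).
        """
        if nu_max is None:
            return self
        return MaterialSet({
            k: (replace(m, nu=nu_max) if m.nu > nu_max else m)
            for k, m in self._materials.items()
        })

    def to_dict(self) -> dict:
        return {
            k: {"E_MPa": m.E, "rho_ton_per_mm3": m.rho, "nu": m.nu}
            for k, m in self._materials.items()
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MaterialSet":
        return cls({
            k: Material(E=v["E_MPa"], rho=v["rho_ton_per_mm3"], nu=v["nu"])
            for k, v in d.items()
        })

    # -- published parameter combinations --------------------------------

    @classmethod
    def homogeneous(cls, E: float, rho: float, nu: float,
                    regions=("HOMOG",)) -> "MaterialSet":
        m = Material(E=E, rho=rho, nu=nu)
        return cls({r: m for r in regions})

    @classmethod
    def tse_reference(cls) -> "MaterialSet":
        """Head-and-neck reference properties (WM = GM, stiff skull).

        Used for the boundary-condition comparison; neck/spine cylinders
        carry skull (bone) properties.
        """
        brain = Material(E=0.497, rho=1.14e-9, nu=0.48)
        csf = Material(E=1.314, rho=1.04e-9, nu=0.4999)
        bone = Material(E=8000.0, rho=4.79e-9, nu=0.22)
        return cls({
            "WM": brain, "GM": brain, "CSF": csf,
            "SKULL": bone, "NECK": bone, "SPINE": bone,
        })

    @classmethod
    def complexity_heterogeneous(cls) -> "MaterialSet":
        """Heterogeneous skull-stripped brain for the complexity comparison."""
        return cls({
            "WM": Material(E=0.03103, rho=1.05e-9, nu=0.45),
            "GM": Material(E=0.01537, rho=1.05e-9, nu=0.45),
            "CSF": Material(E=0.299, rho=1.05e-9, nu=0.45),
        })

    @classmethod
    def complexity_homogeneous(cls) -> "MaterialSet":
        """Single-material brain matched to the heterogeneous comparison."""
        m = Material(E=0.02320, rho=1.04e-9, nu=0.4999)
        return cls({"WM": m, "GM": m, "CSF": m, "HOMOG": m})

    @classmethod
    def csf_sweep(cls, E_csf: float, brain: str = "high") -> "MaterialSet":
        """Material set for one point of the CSF-stiffness sweep.

        ``brain`` selects the (E_GM, E_WM) scenario from
        :data:`BRAIN_STIFFNESS`; the skull stays at 6000 MPa throughout.
        """
        if brain not in BRAIN_STIFFNESS:
            raise ValueError(f"brain must be one of {sorted(BRAIN_STIFFNESS)}")
        e_gm, e_wm = BRAIN_STIFFNESS[brain]
        bone = Material(E=6000.0, rho=3.50e-9, nu=0.22)
        return cls({
            "WM": Material(E=e_wm, rho=1.05e-9, nu=0.45),
            "GM": Material(E=e_gm, rho=1.05e-9, nu=0.45),
            "CSF": Material(E=E_csf, rho=1.00e-9, nu=0.4999),
            "SKULL": bone, "NECK": bone, "SPINE": bone,
        })
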