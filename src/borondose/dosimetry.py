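"""Dose-rate conversions: excess-channel equivalent dose, proton baseline
chains, three-group neutron dose to healthy tissue, and the thermal-capture
competition estimator.

Conventions: the MeV-to-joule constant is deliberately the rounded
1.6e-13 J/MeV so that the published arithmetic reproduces digit for digit;
ICRP flux-to-dose factors are in mrem/h per unit flux and converted with
1 mrem/h = 1e-5 Sv / 3600 s.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .grids import ParticleSpectrum
from .rates import PhantomSpec, TumorSpec, boron_atom_count

__all__ = [
    "J_PER_MEV",
    "MREM_H_TO_SV_S",
    "RadiationWeights",
    "ConversionFactorTable",
    "GroupDose",
    "DoseReport",
    "equivalent_dose_rate_eq2",
    "dose_from_edep",
    "icrp_equiv_dose",
    "sv_to_gy",
    "neutron_group_doses",
    "boron_capture_fraction",
]

#: Rounded joule-per-MeV constant used throughout (configurable per call).
J_PER_MEV = 1.6e-13

#: 1 mrem/h expressed in Sv/s.
MREM_H_TO_SV_S = 1.0e-5 / 3600.0

#: 2200 m/s capture cross-sections (barn) for the competition estimator.
THERMAL_XS_BARN = {"H": 0.332, "C": 0.0035, "N": 1.83, "O": 0.00019, "B10": 3837.0}


@dataclass(frozen=True)
class RadiationWeights:
    """Quality factors Q (dose -> equivalent dose) and weighting factors W_R.

    The fast-neutron quality factor is a band; :meth:`fast_quality`
    interpolates it log-linearly in energy across the fast group.
    """

    quality: Dict[str, float] = field(
        default_factory=lambda: {
            "heavy": 20.0,
            "proton": 1.45,
            "thermal": 2.3,
            "epithermal": 2.0,
        }
    )
    fast_quality_band: Tuple[float, float] = (6.0, 11.0)
    weighting: Dict[str, float] = field(
        default_factory=lambda: {
            "heavy": 20.0,
            "proton": 5.0,
            "thermal": 5.0,
            "epithermal": 10.0,
            "fast": 5.0,
        }
    )

    def __post_init__(self) -> None:
        for factors in (self.quality, self.weighting):
            for name, value in factors.items():
                if value <= 0:
                    raise ValueError(f"factor {name!r} must be positive")
        if min(self.fast_quality_band) <= 0:
            raise ValueError("fast quality band must be positive")

    def fast_quality(self, e_mev, e_lo: float = 0.1, e_hi: float = 130.0):
        """Energy-dependent fast-group Q, log-interpolated across the band."""
        q_lo, q_hi = self.fast_quality_band
        e = np.clip(np.asarray(e_mev, dtype=float), e_lo, e_hi)
        t = np.log(e / e_lo) / np.log(e_hi / e_lo)
        out = q_lo + (q_hi - q_lo) * t
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ConversionFactorTable:
    """Flux-to-dose factors: energy node (MeV) -> mrem/h per unit flux."""

    energies_mev: np.ndarray
    factors: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_mev, dtype=float)
        f = np.asarray(self.factors, dtype=float)
        object.__setattr__(self, "energies_mev", e)
        object.__setattr__(self, "factors", f)
        if e.ndim != 1 or f.shape != e.shape or len(e) < 2:
            raise ValueError("need matching 1-D energy/factor arrays (>= 2 nodes)")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy nodes must be strictly ascending")
        if np.any(f <= 0):
            raise ValueError("conversion factors must be positive")
        if f[-1] <= f[0]:
            raise ValueError("fast-end factor must exceed the thermal-end factor")

    def factor_at(self, e_mev):
        """Log-log interpolation, clamped at both table ends."""
        e = np.clip(
            np.asarray(e_mev, dtype=float), self.energies_mev[0], self.energies_mev[-1]
        )
        out = np.exp(
            np.interp(np.log(e), np.log(self.energies_mev), np.log(self.factors))
        )
        return float(out) if out.ndim == 0 else out

    @classmethod
    def from_packaged(cls, name: str = "icrp21_neutron_flux_to_dose.tsv") -> "ConversionFactorTable":
        ref = resources.files("borondose.data").joinpath(name)
        if not ref.is_file():
            raise FileNotFoundError(f"packaged conversion-factor table {name!r} not found")
        energies, factors = [], []
        with ref.open() as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                e, f = line.split()
                energies.append(float(e))
                factors.append(float(f))
        return cls(np.asarray(energies), np.asarray(factors))


def equivalent_dose_rate_eq2(
    rate: float,
    e_dep_mev: float,
    mass_kg: float,
    q: float,
    j_per_mev: float = J_PER_MEV,
) -> float:
    """Excess equivalent dose rate (EGy/s) from a reaction-rate channel."""
    if mass_kg <= 0:
        raise ValueError("mass must be positive")
    if rate < 0 or e_dep_mev < 0 or q < 0:
        raise ValueError("rate, deposited energy and quality factor must be >= 0")
    return rate * e_dep_mev * j_per_mev / mass_kg * q


def dose_from_edep(edep_mev_per_g: float, j_per_mev: float = J_PER_MEV) -> float:
    """Gy/s per unit proton rate from an energy-deposition density (MeV/g)."""
    if edep_mev_per_g < 0:
        raise ValueError("deposited energy must be nonnegative")
    return edep_mev_per_g * j_per_mev * 1.0e3  # MeV/g -> J/kg


def icrp_equiv_dose(flux: float, cf_mrem_h: float, q: float) -> float:
    """Sv/s from flux (cm^-2 s^-1), a conversion factor (mrem/h per unit flux)
    and a quality factor.  Division by W_R is the Sv->Gy companion step."""
    if flux < 0 or cf_mrem_h < 0 or q < 0:
        raise ValueError("inputs must be nonnegative")
    return flux * cf_mrem_h * q * MREM_H_TO_SV_S


def sv_to_gy(dose_sv_s: float, w_r: float) -> float:
    """Absorbed dose rate from equivalent dose rate via W_R = Sv/Gy."""
    if w_r <= 0:
        raise ValueError("weighting factor must be positive")
    return dose_sv_s / w_r


@dataclass(frozen=True)
class GroupDose:
    """Per-group out-of-field neutron dose rates."""

    flux: float  # cm^-2 s^-1 per proton
    sv_per_s: float
    gy_per_s: float
    q_avg: float
    w_r: float


def neutron_group_doses(
    spectrum: ParticleSpectrum,
    cf: ConversionFactorTable,
    weights: RadiationWeights,
    thermal_cut_mev: float = 4.0e-7,
    fast_cut_mev: float = 0.1,
) -> Dict[str, GroupDose]:
    """Equivalent (Sv/s) and absorbed (Gy/s) dose rates for the three groups.

    Per-bin fluxes are multiplied by the energy-interpolated conversion
    factor and quality factor and summed within each group, so the group
    conversion factor is effectively a flux-weighted average.
    """
    mid = spectrum.grid.midpoints
    bounds = {
        "thermal": (0.0, thermal_cut_mev),
        "epithermal": (thermal_cut_mev, fast_cut_mev),
        "fast": (fast_cut_mev, np.inf),
    }
    e_top = float(spectrum.grid.edges[-1])
    out: Dict[str, GroupDose] = {}
    for group, (lo, hi) in bounds.items():
        mask = (mid >= lo) & (mid < hi)
        phi = spectrum.flux[mask]
        total = float(phi.sum())
        if group == "fast":
            q = weights.fast_quality(mid[mask], e_lo=fast_cut_mev, e_hi=e_top)
        else:
            q = np.full(mask.sum(), weights.quality[group])
        cfs = cf.factor_at(mid[mask]) if np.any(mask) else np.array([])
        sv = float(np.sum(phi * cfs * q)) * MREM_H_TO_SV_S
        w_r = weights.weighting[group]
        q_avg = float(np.sum(phi * q) / total) if total > 0 else 0.0
        out[group] = GroupDose(
            flux=total, sv_per_s=sv, gy_per_s=sv_to_gy(sv, w_r), q_avg=q_avg, w_r=w_r
        )
    return out


def boron_capture_fraction(
    phantom: PhantomSpec,
    tumor: TumorSpec,
    thermal_xs: Optional[Mapping[str, float]] = None,
) -> float:
    """Fraction of phantom-wide thermal-neutron absorptions landing on B-10.

    Absorption competition at 2200 m/s: N_B * sigma_B over the total
    macroscopic absorption inventory (boron plus the phantom's H, C, N, O).
    A small value means adding boron barely perturbs the thermal field, so
    the out-of-field thermal dose is insensitive to the loading.
    """
    xs = dict(THERMAL_XS_BARN)
    if thermal_xs:
        xs.update(thermal_xs)
    n_boron = boron_atom_count(replace(tumor, boron_isotope="B10"))
    boron_term = n_boron * xs["B10"]
    tissue_term = 0.0
    for el, n_atoms in phantom.atom_inventory().items():
        tissue_term += n_atoms * xs.get(el, 0.0)
    if boron_term == 0:
        return 0.0
    return boron_term / (boron_term + tissue_term)


@dataclass
class DoseReport:
    """All dose channels for one scenario case (depth x ppm)."""

    proton_gy_s_edep: float
    proton_sv_s_icrp: float
    proton_gy_s_icrp: float
    pbft_excess_egy_s: float
    ncept_excess_egy_s: float
    neutron_out_of_field: Dict[str, GroupDose]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "proton_gy_s_edep",
            "proton_sv_s_icrp",
            "proton_gy_s_icrp",
            "pbft_excess_egy_s",
            "ncept_excess_egy_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "proton_dose": {
                "gy_per_s_edep": self.proton_gy_s_edep,
                "sv_per_s_icrp": self.proton_sv_s_icrp,
                "gy_per_s_icrp": self.proton_gy_s_icrp,
            },
            "pbft_excess_egy_s": self.pbft_excess_egy_s,
            "ncept_excess_egy_s": self.ncept_excess_egy_s,
            "neutron_out_of_field": {
                g: {
                    "flux": d.flux,
                    "sv_per_s": d.sv_per_s,
                    "gy_per_s": d.gy_per_s,
                    "q_avg": d.q_avg,
                    "w_r": d.w_r,
                }
                for g, d in self.neutron_out_of_field.items()
            },
            "metadata": self.metadata,
        }

    def to_json(self, path: Optional[Path] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_csv(self, path: Path) -> None:
        """Flat channel table: channel, value_Sv_s, value_Gy_s, W_R, Q."""
        rows = [
            ("proton_edep", "", f"{self.proton_gy_s_edep:.6e}", "", "1.45"),
            (
                "proton_icrp",
                f"{self.proton_sv_s_icrp:.6e}",
                f"{self.proton_gy_s_icrp:.6e}",
                "5",
                "1.45",
            ),
            ("pbft_excess", "", f"{self.pbft_excess_egy_s:.6e}", "20", "20"),
            ("ncept_excess", "", f"{self.ncept_excess_egy_s:.6e}", "20", "20"),
        ]
        for group, d in self.neutron_out_of_field.items():
            rows.append(
                (
                    f"neutron_{group}",
                    f"{d.sv_per_s:.6e}",
                    f"{d.gy_per_s:.6e}",
                    f"{d.w_r:g}",
                    f"{d.q_avg:.4g}",
                )
            )
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["channel", "value_Sv_s", "value_Gy_s", "W_R", "Q"])
            writer.writerows(rows)
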