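"""Reaction cross-section tables, 1/v capture model, and group collapse.

Tabulated cross-sections live in two-column TSV files (energy in MeV,
sigma in millibarn) with ``#`` comment headers carrying provenance.  The
thermal-capture channel is modelled analytically with the 1/v law, since
only its thermal anchor value enters the calculation.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Tuple, Union

import numpy as np

from .grids import GridLike

__all__ = [
    "XsFormatError",
    "CrossSectionTable",
    "OneOverVModel",
    "read_xs_table",
    "write_xs_table",
    "load_packaged_table",
    "xs_lookup",
    "one_over_v_xs",
    "group_collapse",
]

#: Packaged fixture for the proton-boron-11 three-alpha channel.
B11_P_3ALPHA = "b11_p_3alpha.tsv"


class XsFormatError(ValueError):
    """Malformed cross-section file (rejected rather than silently fixed)."""


@dataclass(frozen=True)
class CrossSectionTable:
    """Tabulated sigma(E) with lin-lin interpolation inside its validity range."""

    reaction_id: str
    energies: np.ndarray  # MeV, strictly ascending
    sigma: np.ndarray  # mb
    interpolation: str = "lin-lin"

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "sigma", s)
        if e.ndim != 1 or len(e) == 0 or s.shape != e.shape:
            raise XsFormatError("energies and sigma must be equal-length 1-D arrays")
        if np.any(np.diff(e) <= 0):
            raise XsFormatError("energies must be strictly ascending")
        if np.any(s < 0):
            raise XsFormatError("cross-sections must be nonnegative")
        if self.interpolation != "lin-lin":
            raise ValueError(f"unsupported interpolation {self.interpolation!r}")

    @property
    def valid_range(self) -> Tuple[float, float]:
        return (float(self.energies[0]), float(self.energies[-1]))


@dataclass(frozen=True)
class OneOverVModel:
    """1/v capture law ``sigma(E) = sigma0 * sqrt(e0 / E)`` (sigma in barn, E in eV).

    The default anchor is the 2200 m/s value for neutron capture on
    boron-10: 3837 b at 0.0253 eV.
    """

    sigma0: float = 3837.0
    e0: float = 0.0253

    def __post_init__(self) -> None:
        if self.sigma0 <= 0 or self.e0 <= 0:
            raise ValueError("sigma0 and e0 must be positive")


def read_xs_table(source, reaction_id: str = "unknown") -> CrossSectionTable:
    """Parse a two-column (MeV, mb) TSV stream into a validated table."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_xs_table(fh, reaction_id=reaction_id)
    energies, sigma = [], []
    for raw in source:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise XsFormatError(f"expected two columns, got: {line!r}")
        try:
            e, s = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise XsFormatError(f"non-numeric row: {line!r}") from exc
        energies.append(e)
        sigma.append(s)
    if not energies:
        raise XsFormatError("empty cross-section file")
    return CrossSectionTable(reaction_id, np.asarray(energies), np.asarray(sigma))


def write_xs_table(table: CrossSectionTable, dest, provenance: str = "") -> None:
    def _emit(fh) -> None:
        fh.write(f"# reaction: {table.reaction_id}\n")
        if provenance:
            fh.write(f"# provenance: {provenance}\n")
        fh.write("# columns: E_MeV\tsigma_mb\n")
        for e, s in zip(table.energies, table.sigma):
            fh.write(f"{e:.17g}\t{s:.17g}\n")

    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            _emit(fh)
    else:
        _emit(dest)


def load_packaged_table(name: str = B11_P_3ALPHA, reaction_id: str | None = None) -> CrossSectionTable:
    """Load a fixture table shipped under ``borondose/data``."""
    ref = resources.files("borondose.data").joinpath(name)
    if not ref.is_file():
        raise FileNotFoundError(f"packaged cross-section fixture {name!r} not found")
    rid = reaction_id or name.rsplit(".", 1)[0]
    with ref.open() as fh:
        return read_xs_table(fh, reaction_id=rid)


def xs_lookup(table: CrossSectionTable, e) -> Union[float, np.ndarray]:
    """Lin-lin interpolated sigma (mb); zero outside the validity range.

    Energies below the table are sub-threshold and return zero silently;
    energies above return zero with a warning, since the physical
    cross-section there is merely untabulated, not absent.
    """
    e_arr = np.asarray(e, dtype=float)
    if np.any(e_arr < 0):
        raise ValueError("energy must be nonnegative")
    lo, hi = table.valid_range
    if np.any(e_arr > hi):
        warnings.warn(
            f"energy above the {table.reaction_id} table maximum of {hi:g} MeV; "
            "returning 0 for the untabulated tail",
            stacklevel=2,
        )
    out = np.interp(e_arr, table.energies, table.sigma)
    out = np.where((e_arr < lo) | (e_arr > hi), 0.0, out)
    return float(out) if out.ndim == 0 else out


def one_over_v_xs(model: OneOverVModel, e_ev) -> Union[float, np.ndarray]:
    """sigma(E) in barn for neutron energy in eV."""
    e_arr = np.asarray(e_ev, dtype=float)
    if np.any(e_arr <= 0):
        raise ValueError("energy must be positive for the 1/v law")
    out = model.sigma0 * np.sqrt(model.e0 / e_arr)
    return float(out) if out.ndim == 0 else out


def group_collapse(xs: Union[CrossSectionTable, OneOverVModel], grid: GridLike) -> np.ndarray:
    """Per-bin sigma values (mb) evaluated at the grid's bin midpoints.

    Midpoint evaluation (not bin averaging) mirrors the pointwise
    phi(E_i) * sigma(E_i) folding convention used downstream.
    """
    mid = grid.midpoints
    if isinstance(xs, OneOverVModel):
        return np.asarray(one_over_v_xs(xs, mid * 1.0e6)) * 1.0e3  # b -> mb
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(xs_lookup(xs, mid))
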