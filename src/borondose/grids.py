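"""Energy grids and binned particle spectra.

A spectrum is a vector of per-bin flux values (already integrated over the
bin width, in cm^-2 s^-1 per incident proton) attached to an energy grid.
All folding sums downstream are plain discrete sums over bins with no extra
bin-width factor, so the per-bin convention matters and is kept explicit
here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np

__all__ = [
    "GridMismatchError",
    "EnergyGrid",
    "LogEnergyGrid",
    "ParticleSpectrum",
    "read_spectrum_tsv",
    "write_spectrum_tsv",
]


class GridMismatchError(ValueError):
    """Two grid-attached objects were combined on incompatible grids."""


class _GridOps:
    """Behaviour shared by every grid flavour (edges ascending, in MeV)."""

    @property
    def edges(self) -> np.ndarray:
        raise NotImplementedError

    @property
    def nbins(self) -> int:
        return len(self.edges) - 1

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def midpoints(self) -> np.ndarray:
        """Representative bin energies; arithmetic midpoints by default."""
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    def compatible_with(self, other: "_GridOps") -> bool:
        return self.nbins == other.nbins and bool(
            np.allclose(self.edges, other.edges, rtol=1e-12, atol=0.0)
        )


@dataclass(frozen=True)
class EnergyGrid(_GridOps):
    """Uniform multigroup grid; bin ``i`` spans ``[i*w, (i+1)*w)``.

    The default 0.1-MeV width with indices 0..400 covers 0-40.1 MeV, the
    window used by the fusion folding engine.
    """

    bin_width: float = 0.1
    i_min: int = 0
    i_max: int = 400

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.i_min < 0 or self.i_max < self.i_min:
            raise ValueError("need 0 <= i_min <= i_max")

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.i_min, self.i_max + 2, dtype=float) * self.bin_width

    @classmethod
    def covering(cls, e_max: float, bin_width: float = 0.1) -> "EnergyGrid":
        """Smallest grid starting at zero whose top edge reaches ``e_max``."""
        if e_max <= 0:
            raise ValueError("e_max must be positive")
        i_max = int(np.ceil(e_max / bin_width)) - 1
        grid = cls(bin_width=bin_width, i_min=0, i_max=max(i_max, 0))
        if grid.edges[-1] < e_max:  # guard against float round-down
            grid = cls(bin_width=bin_width, i_min=0, i_max=grid.i_max + 1)
        return grid


class LogEnergyGrid(_GridOps):
    """Non-uniform (logarithmically structured) grid with geometric midpoints.

    Used for neutron spectra, which span eleven decades in energy; geometric
    bin midpoints keep the 1/v folding accurate on coarse log bins.
    """

    def __init__(self, edges: Iterable[float]):
        e = np.asarray(list(edges), dtype=float)
        if e.ndim != 1 or len(e) < 2:
            raise ValueError("need at least two edges")
        if np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly ascending")
        if e[0] <= 0:
            raise ValueError("log grid edges must be positive")
        self._edges = e

    @property
    def edges(self) -> np.ndarray:
        return self._edges

    @property
    def midpoints(self) -> np.ndarray:
        e = self._edges
        return np.sqrt(e[:-1] * e[1:])

    @classmethod
    def spanning(cls, e_min: float, e_max: float, per_decade: int = 48) -> "LogEnergyGrid":
        if not 0 < e_min < e_max:
            raise ValueError("need 0 < e_min < e_max")
        n = max(int(np.ceil(per_decade * np.log10(e_max / e_min))), 1)
        return cls(np.geomspace(e_min, e_max, n + 1))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LogEnergyGrid) and self.compatible_with(other)

    def __repr__(self) -> str:
        return (
            f"LogEnergyGrid({self._edges[0]:.3g}..{self._edges[-1]:.3g} MeV,"
            f" {self.nbins} bins)"
        )


GridLike = Union[EnergyGrid, LogEnergyGrid]


@dataclass
class ParticleSpectrum:
    """Per-bin flux phi(E_i) on an energy grid, per incident proton."""

    particle: str
    grid: GridLike
    flux: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.particle not in ("proton", "neutron"):
            raise ValueError(f"unknown particle {self.particle!r}")
        self.flux = np.asarray(self.flux, dtype=float)
        if self.flux.shape != (self.grid.nbins,):
            raise GridMismatchError(
                f"flux length {self.flux.shape} does not match grid "
                f"({self.grid.nbins} bins)"
            )
        if np.any(self.flux < 0):
            raise ValueError("flux values must be nonnegative")

    def total(self) -> float:
        return float(self.flux.sum())

    def group_flux(self, e_lo: float, e_hi: float) -> float:
        """Summed flux of bins whose midpoint lies in ``[e_lo, e_hi)``."""
        mid = self.grid.midpoints
        mask = (mid >= e_lo) & (mid < e_hi)
        return float(self.flux[mask].sum())

    def scaled(self, factor: float) -> "ParticleSpectrum":
        if factor < 0:
            raise ValueError("scale factor must be nonnegative")
        return ParticleSpectrum(self.particle, self.grid, self.flux * factor, dict(self.meta))


_COLUMNS = "E_low_MeV\tE_high_MeV\tflux_per_cm2_s_per_proton"


def write_spectrum_tsv(spectrum: ParticleSpectrum, dest) -> None:
    """Serialize a spectrum to TSV with a provenance header."""

    def _emit(fh) -> None:
        fh.write(f"# borondose spectrum\n# particle: {spectrum.particle}\n")
        rule = "geometric" if isinstance(spectrum.grid, LogEnergyGrid) else "arithmetic"
        fh.write(f"# midpoint_rule: {rule}\n")
        prov = spectrum.meta.get("provenance", "synthetic")
        fh.write(f"# provenance: {prov}\n")
        fh.write(f"# columns: {_COLUMNS}\n")
        e = spectrum.grid.edges
        for lo, hi, phi in zip(e[:-1], e[1:], spectrum.flux):
            fh.write(f"{lo:.17g}\t{hi:.17g}\t{phi:.17g}\n")

    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            _emit(fh)
    else:
        _emit(dest)


def read_spectrum_tsv(source) -> ParticleSpectrum:
    """Inverse of :func:`write_spectrum_tsv`; round-trips values bit-exactly."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_spectrum_tsv(fh)
    particle = "proton"
    rule = "arithmetic"
    lows, highs, flux = [], [], []
    for raw in source:
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("particle:"):
                particle = body.split(":", 1)[1].strip()
            elif body.startswith("midpoint_rule:"):
                rule = body.split(":", 1)[1].strip()
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"bad spectrum row: {line!r}")
        lows.append(float(parts[0]))
        highs.append(float(parts[1]))
        flux.append(float(parts[2]))
    if not lows:
        raise ValueError("empty spectrum file")
    edges = np.array(lows + [highs[-1]], dtype=float)
    if not np.allclose(edges[1:-1], np.asarray(highs[:-1]), rtol=0, atol=0):
        raise ValueError("bin edges are not contiguous")
    grid: GridLike
    if rule == "geometric":
        grid = LogEnergyGrid(edges)
    else:
        widths = np.diff(edges)
        w = widths[0]
        if not np.allclose(widths, w, rtol=1e-9):
            raise ValueError("arithmetic spectrum grid is not uniform")
        i_min = int(round(edges[0] / w))
        grid = EnergyGrid(bin_width=w, i_min=i_min, i_max=i_min + len(widths) - 1)
    return ParticleSpectrum(particle, grid, np.asarray(flux), {"provenance": "file"})
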