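"""Core data model: mass spectra, peaks, and peak tables.

A GCxGC-TOF peak detection export contains, per detected compound, a
first-dimension retention time (seconds on the primary column), a
second-dimension retention time (seconds within the modulation period)
and a unit-mass spectrum of relative abundances.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "Peak",
    "PeakTable",
    "PeakTableError",
    "SpectrumError",
    "ValidationError",
]


class PeakTableError(ValueError):
    """Base class for peak-table data errors."""


class SpectrumError(PeakTableError):
    """Raised for malformed or invalid mass spectra."""


class ValidationError(PeakTableError):
    """Raised when a table violates a structural invariant."""


@dataclass(frozen=True)
class Spectrum:
    """Sparse unit-mass spectrum: integer m/z -> relative abundance (>= 0).

    Abundances are kept exactly as read from the export; no renormalisation
    is performed, because exported values already represent relative
    abundances and rescaling would not change either Pearson or cosine
    similarity.
    """

    intensities: Mapping[int, float]

    def __post_init__(self) -> None:
        clean: dict[int, float] = {}
        for mz, inten in self.intensities.items():
            m = int(mz)
            v = float(inten)
            if m <= 0:
                raise SpectrumError(f"m/z must be a positive integer, got {mz!r}")
            if not np.isfinite(v) or v < 0:
                raise SpectrumError(f"abundance at m/z {m} must be finite and >= 0, got {inten!r}")
            clean[m] = v
        object.__setattr__(self, "intensities", MappingProxyType(dict(sorted(clean.items()))))

    def __len__(self) -> int:
        return len(self.intensities)

    def __getitem__(self, mz: int) -> float:
        return self.intensities[mz]

    def get(self, mz: int, default: float = 0.0) -> float:
        return self.intensities.get(mz, default)

    def items(self):
        return self.intensities.items()

    def __eq__(self, other) -> bool:  # MappingProxyType breaks dataclass eq
        if not isinstance(other, Spectrum):
            return NotImplemented
        return dict(self.intensities) == dict(other.intensities)

    def __hash__(self) -> int:
        return hash(tuple(self.intensities.items()))

    @property
    def mz(self) -> np.ndarray:
        """Sorted m/z values with recorded abundance."""
        return np.fromiter(self.intensities.keys(), dtype=np.int64, count=len(self.intensities))

    @property
    def abundances(self) -> np.ndarray:
        return np.fromiter(self.intensities.values(), dtype=np.float64, count=len(self.intensities))

    @property
    def base_peak(self) -> int:
        """m/z of the most abundant fragment."""
        if not self.intensities:
            raise SpectrumError("empty spectrum has no base peak")
        return max(self.intensities, key=self.intensities.get)

    def is_blank(self) -> bool:
        """True when no fragment has positive abundance."""
        return not any(v > 0 for v in self.intensities.values())


@dataclass(frozen=True)
class Peak:
    """One detected compound: retention times in seconds plus its spectrum."""

    rt1: float
    rt2: float
    spectrum: Spectrum
    label: str | None = None

    def __post_init__(self) -> None:
        if self.rt1 < 0 or self.rt2 < 0:
            raise ValidationError(
                f"retention times must be >= 0 s, got rt1={self.rt1}, rt2={self.rt2}"
            )

    @property
    def total_rt(self) -> float:
        """Total elution time rt1 + rt2 (s); the elution-order key."""
        return self.rt1 + self.rt2


@dataclass(frozen=True)
class PeakTable:
    """Ordered peak collection for one chromatogram.

    Row order of the source file is preserved: peak index == row index.
    """

    sample_id: str
    peaks: tuple[Peak, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        object.__setattr__(self, "peaks", tuple(self.peaks))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, idx: int) -> Peak:
        return self.peaks[idx]

    def rt1(self) -> np.ndarray:
        """First-dimension retention times (s), in row order."""
        return np.array([p.rt1 for p in self.peaks], dtype=np.float64)

    def rt2(self) -> np.ndarray:
        """Second-dimension retention times (s), in row order."""
        return np.array([p.rt2 for p in self.peaks], dtype=np.float64)

    def total_rt(self) -> np.ndarray:
        return self.rt1() + self.rt2()

    def with_peaks(self, peaks: Sequence[Peak], sample_id: str | None = None) -> "PeakTable":
        """Copy of the table carrying a new peak list."""
        return PeakTable(sample_id=sample_id or self.sample_id, peaks=tuple(peaks))
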