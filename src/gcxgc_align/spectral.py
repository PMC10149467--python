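"""Mass-spectral similarity scoring.

Two spectra are compared on the union of their m/z grids (a mass absent
from one spectrum is evidence, and enters as zero). The user chooses
Pearson correlation or cosine similarity, optionally after a power
transformation I -> I^a * m^b that up-weights heavy fragments — useful
when homologous compounds share the same low-mass fragments and differ
only in their high-mass ends. The widely used exponents a = 0.53 and
b = 1.3 are the defaults.

Every matching algorithm in this package gates on the same rule: a pair
whose (floored, see :func:`gated_similarity`) similarity falls below the
configured threshold is never a match.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .peaks import Spectrum, SpectrumError

__all__ = [
    "SimilarityConfig",
    "transform_spectrum",
    "pair_vectors",
    "spectral_similarity",
    "gated_similarity",
]


@dataclass(frozen=True)
class SimilarityConfig:
    """How two mass spectra are compared.

    method              "pearson" or "cosine"
    transform           apply the power transformation before comparing
    intensity_exponent  a in I^a (default 0.53)
    mz_exponent         b in m^b (default 1.3)
    threshold           minimum similarity in [0, 1] for a match
    """

    method: str = "cosine"
    transform: bool = True
    intensity_exponent: float = 0.53
    mz_exponent: float = 1.3
    threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.method not in ("pearson", "cosine"):
            raise ValueError(f"unknown similarity method {self.method!r}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must lie in [0, 1], got {self.threshold}")
        if self.intensity_exponent <= 0 or self.mz_exponent <= 0:
            raise ValueError("exponents must be > 0")


def transform_spectrum(s: Spectrum, cfg: SimilarityConfig) -> Spectrum:
    """Power transformation (m, I) -> (m, I^a * m^b); keys unchanged.

    Zero intensities stay zero, and the intensity ordering at any fixed
    m/z is preserved (x^a is increasing for a > 0).
    """
    a, b = cfg.intensity_exponent, cfg.mz_exponent
    return Spectrum({mz: (inten**a) * (mz**b) for mz, inten in s.items()})


def pair_vectors(a: Spectrum, b: Spectrum) -> tuple[np.ndarray, np.ndarray]:
    """Expand two spectra over the union of their m/z keys.

    Returns two equal-length vectors in identical (ascending m/z) key
    order, absent keys filled with zero.
    """
    if len(a) == 0 and len(b) == 0:
        raise SpectrumError("cannot pair two empty spectra")
    grid = sorted(set(a.intensities) | set(b.intensities))
    va = np.array([a.get(m) for m in grid], dtype=np.float64)
    vb = np.array([b.get(m) for m in grid], dtype=np.float64)
    return va, vb


def spectral_similarity(a: Spectrum, b: Spectrum, cfg: SimilarityConfig = SimilarityConfig()) -> float:
    """Pearson or cosine similarity, after the optional transformation.

    Conventions for degenerate inputs: cosine with a zero vector is 0,
    and Pearson with a constant vector is 0 (no variance, no evidence of
    association).
    """
    if cfg.transform:
        a = transform_spectrum(a, cfg)
        b = transform_spectrum(b, cfg)
    va, vb = pair_vectors(a, b)
    if cfg.method == "cosine":
        na = np.linalg.norm(va)
        nb = np.linalg.norm(vb)
        if na == 0.0 or nb == 0.0:
            return 0.0
        return float(np.dot(va, vb) / (na * nb))
    # Pearson on the union grid (zeros included).
    va = va - va.mean()
    vb = vb - vb.mean()
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(va, vb) / (na * nb))


def gated_similarity(a: Spectrum, b: Spectrum, cfg: SimilarityConfig = SimilarityConfig()) -> float:
    """Similarity floored at 0 for threshold gating.

    Thresholds are expressed on a [0, 1] scale; an anti-correlated
    spectrum pair is as much a non-match as an orthogonal one.
    """
    return max(0.0, spectral_similarity(a, b, cfg))
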