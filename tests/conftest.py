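"""Shared fixtures: tiny hand-made tables and seeded synthetic pairs."""
from __future__ import annotations

import pytest

from gcxgc_align import (
    DistortionConfig,
    Peak,
    PeakTable,
    Spectrum,
    distort_table,
    make_benchmark_pair,
    make_reference_table,
    make_spectrum_library,
)


def spectrum(d: dict[int, float]) -> Spectrum:
    return Spectrum(d)


def small_synthetic_pair(
    n_peaks: int = 30,
    seed: int = 42,
    **distortion,
):
    """A compact (ref, aligned, truth) bundle with custom distortion."""
    library = make_spectrum_library(n_peaks + 5, seed=seed)
    ref = make_reference_table(library, n_peaks, seed=seed + 1)
    cfg = DistortionConfig(seed=seed + 2, **distortion)
    aligned, truth = distort_table(ref, cfg)
    return ref, aligned, truth


@pytest.fixture(scope="session")
def small_table() -> PeakTable:
    """Five peaks with mutually dissimilar spectra, sorted by total RT."""
    specs = [
        {43: 999, 71: 300, 99: 120},
        {57: 999, 85: 410, 113: 90},
        {91: 999, 65: 350, 39: 150},
        {105: 999, 120: 500, 77: 200},
        {149: 999, 167: 280, 279: 100},
    ]
    peaks = [
        Peak(rt1=100.0 + 50.0 * i, rt2=1.0 + 0.5 * i, spectrum=Spectrum(s), label=f"p{i}")
        for i, s in enumerate(specs)
    ]
    return PeakTable(sample_id="small", peaks=tuple(peaks))


@pytest.fixture(scope="session")
def midsize_pair():
    """30-peak reference plus a mildly shifted copy with known truth."""
    return small_synthetic_pair(
        n_peaks=30,
        seed=7,
        warp1=(1.0, 5.0),
        warp2=(1.0, 0.1),
        jitter1=0.2,
        jitter2=0.01,
        spectral_noise=0.02,
    )


@pytest.fixture(scope="session")
def benchmark_same():
    return make_benchmark_pair("same_system", seed=42)


@pytest.fixture(scope="session")
def benchmark_cross():
    return make_benchmark_pair("cross_system", seed=42)
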