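"""Synthetic chromatogram pairs with known warps and correspondences.

Real validation data for GCxGC alignment require a measured dataset and
a manual annotation step; this module instead fabricates a reference
peak table and a distorted copy whose ground truth is known exactly:
which aligned peak corresponds to which reference peak, and which
affine warp each dimension experienced. That makes anchor precision and
recall computable, and warp recovery checkable against the generating
coefficients.

Two presets mirror the regimes seen between instrument-maintenance
events: ``same_system`` pairs (runs from one column set) differ by a
small constant offset plus jitter, while ``cross_system`` pairs (after
a column replacement in both dimensions) add multiplicative drift,
peak dropout and spurious insertions.

The generator emulates exported peak tables, not raw chromatography: no
modulation, peak shapes or co-elution — spectra are random sparse
fragment sets kept mutually dissimilar so matches are unambiguous.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .peaks import Peak, PeakTable, Spectrum, ValidationError
from .spectral import SimilarityConfig, spectral_similarity

__all__ = [
    "DistortionConfig",
    "GroundTruth",
    "PRESETS",
    "make_spectrum_library",
    "make_reference_table",
    "distort_table",
    "make_benchmark_pair",
]

# raw (untransformed) cosine; library entries are kept below this
_LIBRARY_MAX_COSINE = 0.5
_RAW_COSINE = SimilarityConfig(method="cosine", transform=False, threshold=0.0)


@dataclass(frozen=True)
class DistortionConfig:
    """How the aligned copy differs from the reference.

    warp1/warp2      affine (a, b): rt -> a*rt + b seconds, per dimension
    jitter1/jitter2  sd of additive retention-time noise (s)
    dropout          probability a reference peak is absent from the copy
    insertions       count of spurious peaks with fresh spectra
    spectral_noise   sd of per-fragment multiplicative log-normal noise
    """

    warp1: tuple[float, float] = (1.0, 0.0)
    warp2: tuple[float, float] = (1.0, 0.0)
    jitter1: float = 0.0
    jitter2: float = 0.0
    dropout: float = 0.0
    insertions: int = 0
    spectral_noise: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.warp1[0] <= 0 or self.warp2[0] <= 0:
            raise ValidationError("warp slopes must be > 0 (order-preserving)")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValidationError("dropout must lie in [0, 1]")
        if min(self.jitter1, self.jitter2, self.spectral_noise) < 0 or self.insertions < 0:
            raise ValidationError("noise magnitudes and insertion count must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Known correspondence ref_index -> aligned index (None = absent)."""

    correspondence: dict[int, int | None]
    config: DistortionConfig

    def __post_init__(self) -> None:
        present = [a for a in self.correspondence.values() if a is not None]
        if len(set(present)) != len(present):
            raise ValidationError("ground-truth correspondence must be injective")

    def matched(self) -> dict[int, int]:
        return {r: a for r, a in self.correspondence.items() if a is not None}


def _random_spectrum(rng: np.random.Generator, mz_range: tuple[int, int], n_frag: int) -> Spectrum:
    lo, hi = mz_range
    mzs = rng.choice(np.arange(lo, hi + 1), size=n_frag, replace=False)
    intens = rng.uniform(10.0, 400.0, size=n_frag)
    intens[rng.integers(n_frag)] = 999.0  # one dominant fragment
    return Spectrum(dict(zip(mzs.tolist(), intens.tolist())))


def _fresh_spectrum(
    rng: np.random.Generator,
    existing: list[Spectrum],
    mz_range: tuple[int, int],
    frag_range: tuple[int, int],
    max_tries: int = 200,
) -> Spectrum:
    """Rejection-sample a spectrum dissimilar (cosine < 0.5) to all existing."""
    for _ in range(max_tries):
        n_frag = int(rng.integers(frag_range[0], frag_range[1] + 1))
        cand = _random_spectrum(rng, mz_range, n_frag)
        if all(spectral_similarity(cand, s, _RAW_COSINE) < _LIBRARY_MAX_COSINE for s in existing):
            return cand
    raise ValidationError(
        f"could not draw a spectrum with pairwise cosine < {_LIBRARY_MAX_COSINE} "
        f"after {max_tries} tries; widen mz_range or lower the library size"
    )


def make_spectrum_library(
    n: int,
    mz_range: tuple[int, int] = (29, 350),
    peaks_per_spectrum: tuple[int, int] = (6, 15),
    seed: int = 42,
) -> list[Spectrum]:
    """n mutually dissimilar sparse spectra (pairwise raw cosine < 0.5)."""
    if n < 1:
        raise ValidationError("library size must be >= 1")
    rng = np.random.default_rng(seed)
    library: list[Spectrum] = []
    for _ in range(n):
        library.append(_fresh_spectrum(rng, library, mz_range, peaks_per_spectrum))
    return library


def make_reference_table(
    library: list[Spectrum],
    n_peaks: int,
    rt1_range: tuple[float, float] = (60.0, 2400.0),
    rt2_range: tuple[float, float] = (0.5, 5.5),
    seed: int = 42,
    sample_id: str = "reference",
) -> PeakTable:
    """Reference table: uniform RTs (sorted by total RT), distinct spectra."""
    if n_peaks > len(library):
        raise ValidationError(f"n_peaks={n_peaks} exceeds library size {len(library)}")
    rng = np.random.default_rng(seed)
    rt1 = rng.uniform(*rt1_range, size=n_peaks)
    rt2 = rng.uniform(*rt2_range, size=n_peaks)
    chosen = rng.permutation(len(library))[:n_peaks]
    peaks = [
        Peak(rt1=float(t1), rt2=float(t2), spectrum=library[int(c)], label=f"C{int(c):03d}")
        for t1, t2, c in zip(rt1, rt2, chosen)
    ]
    peaks.sort(key=lambda p: p.total_rt)
    return PeakTable(sample_id=sample_id, peaks=tuple(peaks))


def _perturb_spectrum(s: Spectrum, rng: np.random.Generator, sigma: float) -> Spectrum:
    if sigma == 0.0:
        return s
    return Spectrum(
        {mz: inten * float(rng.lognormal(0.0, sigma)) for mz, inten in s.items()}
    )


def distort_table(ref: PeakTable, cfg: DistortionConfig) -> tuple[PeakTable, GroundTruth]:
    """Apply the configured warp/noise/dropout/insertions to a reference.

    The returned aligned table is sorted by total RT (as an export would
    be) and the ground truth maps each reference index to its surviving
    aligned index, or None when dropped. Inserted peaks never appear in
    the correspondence.
    """
    rng = np.random.default_rng(cfg.seed)
    (a1, b1), (a2, b2) = cfg.warp1, cfg.warp2
    records: list[tuple[int | None, Peak]] = []  # (ref_index or None, peak)
    for i, p in enumerate(ref):
        if rng.random() < cfg.dropout:
            continue
        t1 = a1 * p.rt1 + b1 + (rng.normal(0.0, cfg.jitter1) if cfg.jitter1 else 0.0)
        t2 = a2 * p.rt2 + b2 + (rng.normal(0.0, cfg.jitter2) if cfg.jitter2 else 0.0)
        spec = _perturb_spectrum(p.spectrum, rng, cfg.spectral_noise)
        records.append((i, Peak(rt1=max(0.0, t1), rt2=max(0.0, t2), spectrum=spec, label=p.label)))

    if cfg.insertions:
        existing = [p.spectrum for p in ref]
        rt1s = ref.rt1()
        rt2s = ref.rt2()
        lo1, hi1 = a1 * rt1s.min() + b1, a1 * rt1s.max() + b1
        lo2, hi2 = a2 * rt2s.min() + b2, a2 * rt2s.max() + b2
        for k in range(cfg.insertions):
            spec = _fresh_spectrum(rng, existing, (29, 350), (6, 15))
            existing.append(spec)
            records.append(
                (
                    None,
                    Peak(
                        rt1=max(0.0, float(rng.uniform(lo1, hi1))),
                        rt2=max(0.0, float(rng.uniform(lo2, hi2))),
                        spectrum=spec,
                        label=f"spurious_{k}",
                    ),
                )
            )

    records.sort(key=lambda r: r[1].total_rt)
    correspondence: dict[int, int | None] = {i: None for i in range(len(ref))}
    for j, (ref_i, _) in enumerate(records):
        if ref_i is not None:
            correspondence[ref_i] = j
    aligned = PeakTable(sample_id=f"{ref.sample_id}_distorted", peaks=tuple(p for _, p in records))
    return aligned, GroundTruth(correspondence=correspondence, config=cfg)


# Preset study conditions. same_system: runs on one column set differ by a
# small constant offset plus jitter, with every compound present in both
# runs. cross_system: a column replacement in both dimensions adds offset
# plus multiplicative drift (up to ~25 s in dim 1 at the end of the
# program, dominated by the dim-2 phase shift), peak dropout and spurious
# detections.
PRESETS: dict[str, DistortionConfig] = {
    "same_system": DistortionConfig(
        warp1=(1.0, 8.0),
        warp2=(1.0, 0.15),
        jitter1=0.3,
        jitter2=0.01,
        dropout=0.0,
        insertions=0,
        spectral_noise=0.03,
    ),
    "cross_system": DistortionConfig(
        warp1=(1.003, 18.0),
        warp2=(0.97, 0.3),
        jitter1=0.5,
        jitter2=0.02,
        dropout=0.03,
        insertions=3,
        spectral_noise=0.05,
    ),
}

_DEFAULT_N_PEAKS = 150


def make_benchmark_pair(
    preset: str = "same_system",
    seed: int = 42,
    n_peaks: int = _DEFAULT_N_PEAKS,
) -> tuple[PeakTable, PeakTable, GroundTruth]:
    """Deterministic (reference, aligned, truth) bundle for one preset."""
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    lib_seed, table_seed, distort_seed = (int(s) for s in np.random.SeedSequence(seed).generate_state(3) % (2**31))
    library = make_spectrum_library(n_peaks + 8, seed=lib_seed)
    ref = make_reference_table(library, n_peaks, seed=table_seed, sample_id=f"{preset}_ref")
    cfg = replace(PRESETS[preset], seed=distort_seed)
    aligned, truth = distort_table(ref, cfg)
    return ref, aligned, truth
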