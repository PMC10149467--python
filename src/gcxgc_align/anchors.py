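"""Anchor-peak detection between a reference and an aligned peak table.

An anchor is a peak confidently identified in both chromatograms; the
time-shift correction is later fitted through the anchors only. Six
selection strategies from the alignment literature are provided:

* best-bidirectional-hit matching with Gaussian retention-time
  penalties per dimension (:func:`find_anchors_bipace`);
* nearest-neighbour search in z-scored time space with top spectral
  similarity (:func:`find_anchors_disco`);
* a static raw-seconds search window with top spectral similarity
  (:func:`find_anchors_msort`);
* exhaustive pairing under a weighted distance/similarity score
  (:func:`find_anchors_pam`);
* the combination of the neighbourhood discrimination rule with the
  weighted selection rule (:func:`find_anchors_tntda`);
* local sequence alignment of the two elution orders by dynamic
  programming (:func:`smith_waterman_anchors`).

All of them gate on the same spectral-similarity threshold and return a
one-to-one :class:`AnchorSet`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import canberra as _canberra

from dataclasses import replace as _dc_replace

from .peaks import PeakTable, ValidationError
from .spectral import SimilarityConfig, gated_similarity


def _pair_sim_fn(ref: PeakTable, aln: PeakTable, cfg: SimilarityConfig):
    """Gated pairwise similarity with the power transform hoisted out.

    Transforming each spectrum once per table instead of once per pair
    changes nothing numerically (the transform is per-spectrum) but
    turns the O(n*m) inner loop into pure vector comparisons.
    """
    if cfg.transform:
        from .spectral import transform_spectrum

        sref = [transform_spectrum(p.spectrum, cfg) for p in ref]
        saln = [transform_spectrum(q.spectrum, cfg) for q in aln]
        cfg = _dc_replace(cfg, transform=False)
    else:
        sref = [p.spectrum for p in ref]
        saln = [q.spectrum for q in aln]

    def sim(i: int, j: int) -> float:
        return gated_similarity(sref[i], saln[j], cfg)

    return sim

__all__ = [
    "AnchorPair",
    "AnchorSet",
    "BiPACEConfig",
    "PAMConfig",
    "MSortConfig",
    "NeighborhoodConfig",
    "SmithWatermanConfig",
    "zscore_times",
    "peak_distance",
    "candidate_neighbors",
    "bipace_pair_score",
    "pam_match_score",
    "find_anchors_bipace",
    "find_anchors_disco",
    "find_anchors_msort",
    "find_anchors_pam",
    "find_anchors_tntda",
    "smith_waterman_anchors",
    "find_anchors",
    "ALGORITHMS",
]


@dataclass(frozen=True)
class AnchorPair:
    """One matched reference/aligned peak with its scores.

    ``similarity`` is the (gated) spectral similarity in [0, 1];
    ``score`` is the algorithm's own selection score (similarity for the
    window algorithms, the weighted match score for PAM/TNT-DA, the
    penalty-weighted similarity for the bidirectional-hit algorithm, the
    alignment-matrix cell value for the sequence aligner).
    """

    ref_index: int
    aln_index: int
    similarity: float
    score: float


@dataclass(frozen=True)
class AnchorSet:
    """One-to-one matched pairs plus the provenance of the run."""

    pairs: tuple[AnchorPair, ...]
    algorithm: str
    config: object | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        refs = [p.ref_index for p in self.pairs]
        alns = [p.aln_index for p in self.pairs]
        if len(set(refs)) != len(refs) or len(set(alns)) != len(alns):
            raise ValidationError("anchor set is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def as_mapping(self) -> dict[int, int]:
        return {p.ref_index: p.aln_index for p in self.pairs}


# ---------------------------------------------------------------------------
# configurations


@dataclass(frozen=True)
class BiPACEConfig:
    """Gaussian penalty matching: D1/D2 tolerances (s) and T1/T2 cutoffs.

    A pair's score is exp(-dt1^2 / 2 D1^2) * exp(-dt2^2 / 2 D2^2) * s.
    A penalty factor below its T cutoff discards the pair, which turns
    the cutoffs into an implicit search window (T=0 disables the gate;
    the tight published setting is 0.99).
    """

    D1: float = 100.0
    D2: float = 0.8
    T1: float = 0.5
    T2: float = 0.5
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)

    def __post_init__(self) -> None:
        if self.D1 <= 0 or self.D2 <= 0:
            raise ValueError("D1 and D2 must be > 0")
        if not (0 <= self.T1 <= 1 and 0 <= self.T2 <= 1):
            raise ValueError("T1 and T2 must lie in [0, 1]")


@dataclass(frozen=True)
class PAMConfig:
    """Weighted selection rule w/(1+D) + (1-w) S over all peak pairs."""

    w: float = 0.8
    distance: str = "canberra"
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if self.distance not in ("canberra", "euclidean"):
            raise ValueError(f"unknown distance {self.distance!r}")


@dataclass(frozen=True)
class MSortConfig:
    """Static search window, half-widths in raw seconds per dimension."""

    max_shift_1: float = 25.0
    max_shift_2: float = 0.5
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)

    def __post_init__(self) -> None:
        if self.max_shift_1 <= 0 or self.max_shift_2 <= 0:
            raise ValueError("window half-widths must be > 0")


@dataclass(frozen=True)
class NeighborhoodConfig:
    """Nearest-peak discrimination rule in z-scored time space.

    ``fraction`` of the aligned table (default 20%) nearest to the
    inspected reference peak is considered; the count is rounded up so a
    non-empty table always yields at least one candidate.
    """

    fraction: float = 0.20
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must lie in (0, 1]")
        if self.distance not in ("canberra", "euclidean"):
            raise ValueError(f"unknown distance {self.distance!r}")


@dataclass(frozen=True)
class SmithWatermanConfig:
    """Local-alignment scoring; match/mismatch decided by the spectral gate."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -1.0
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)


# ---------------------------------------------------------------------------
# geometric helpers


def zscore_times(table: PeakTable) -> np.ndarray:
    """Standardise each retention dimension to zero mean, unit sample sd.

    Returns an (n, 2) array of (z1, z2) rows. Requires at least two
    peaks and non-zero spread in both dimensions.
    """
    if len(table) < 2:
        raise ValidationError(f"{table.sample_id}: need >= 2 peaks to z-score retention times")
    out = np.empty((len(table), 2), dtype=np.float64)
    for d, x in enumerate((table.rt1(), table.rt2())):
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValidationError(f"{table.sample_id}: zero variance in dimension {d + 1}")
        out[:, d] = (x - x.mean()) / sd
    return out


def peak_distance(p: Sequence[float], q: Sequence[float], metric: str = "euclidean") -> float:
    """Distance between two (z1, z2) points.

    euclidean: sqrt(dz1^2 + dz2^2); canberra: sum |p_i - q_i| /
    (|p_i| + |q_i|) with 0/0 terms contributing 0.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if metric == "euclidean":
        return float(np.linalg.norm(p - q))
    if metric == "canberra":
        return float(_canberra(p, q))
    raise ValueError(f"unknown metric {metric!r}")


def candidate_neighbors(
    ref_point: Sequence[float],
    aligned_points: np.ndarray,
    cfg: NeighborhoodConfig = NeighborhoodConfig(),
) -> list[int]:
    """Indices of the ceil(fraction*N) aligned peaks nearest to ``ref_point``.

    Sorted by distance ascending; ties broken by index (stable sort) so
    candidate order is deterministic.
    """
    n = len(aligned_points)
    if n == 0:
        return []
    k = math.ceil(cfg.fraction * n)
    d = np.array([peak_distance(ref_point, ap, cfg.distance) for ap in aligned_points])
    order = np.argsort(d, kind="stable")
    return [int(i) for i in order[:k]]


# ---------------------------------------------------------------------------
# pair scores


def bipace_pair_score(dt1: float, dt2: float, cfg: BiPACEConfig, s: float) -> float:
    """Gaussian-penalty pair score; 0 when a penalty falls below its cutoff."""
    p1 = math.exp(-(dt1 * dt1) / (2.0 * cfg.D1 * cfg.D1))
    p2 = math.exp(-(dt2 * dt2) / (2.0 * cfg.D2 * cfg.D2))
    if p1 < cfg.T1 or p2 < cfg.T2:
        return 0.0
    return p1 * p2 * s


def pam_match_score(distance: float, similarity: float, w: float) -> float:
    """Weighted match score w/(1+D) + (1-w) S, in [0, 1]."""
    return w / (1.0 + distance) + (1.0 - w) * similarity


# ---------------------------------------------------------------------------
# one-to-one conflict resolution


def _resolve_one_to_one(candidates: Iterable[AnchorPair], ref: PeakTable, aln: PeakTable) -> list[AnchorPair]:
    """Greedy conflict resolution: keep the higher-scoring claim.

    Ties break by smaller total-retention-time difference, then lower
    reference index — deterministic, and a duplicated aligned peak would
    corrupt the warp fit downstream.
    """

    def key(p: AnchorPair):
        dt = abs(ref[p.ref_index].total_rt - aln[p.aln_index].total_rt)
        return (-p.score, dt, p.ref_index, p.aln_index)

    taken_ref: set[int] = set()
    taken_aln: set[int] = set()
    kept: list[AnchorPair] = []
    for p in sorted(candidates, key=key):
        if p.ref_index in taken_ref or p.aln_index in taken_aln:
            continue
        taken_ref.add(p.ref_index)
        taken_aln.add(p.aln_index)
        kept.append(p)
    kept.sort(key=lambda p: p.ref_index)
    return kept


# ---------------------------------------------------------------------------
# the six algorithms


def find_anchors_bipace(ref: PeakTable, aln: PeakTable, cfg: BiPACEConfig = BiPACEConfig()) -> AnchorSet:
    """Best bidirectional hits under the Gaussian-penalty pair score.

    A pair (p, q) is an anchor iff q maximises the score among all
    aligned peaks for p AND p maximises it among all reference peaks for
    q, with a strictly positive score. Similarities below the configured
    threshold contribute a zero score.
    """
    n, m = len(ref), len(aln)
    if n == 0 or m == 0:
        return AnchorSet((), "bipace2d", cfg)
    sim_fn = _pair_sim_fn(ref, aln, cfg.similarity)
    scores = np.zeros((n, m), dtype=np.float64)
    sims = np.zeros((n, m), dtype=np.float64)
    for i, p in enumerate(ref):
        for j, q in enumerate(aln):
            s = sim_fn(i, j)
            sims[i, j] = s
            if s < cfg.similarity.threshold:
                continue
            scores[i, j] = bipace_pair_score(p.rt1 - q.rt1, p.rt2 - q.rt2, cfg, s)
    pairs = []
    best_j = scores.argmax(axis=1)
    best_i = scores.argmax(axis=0)
    for i in range(n):
        j = int(best_j[i])
        if scores[i, j] > 0.0 and int(best_i[j]) == i:
            pairs.append(AnchorPair(i, j, similarity=float(sims[i, j]), score=float(scores[i, j])))
    return AnchorSet(tuple(pairs), "bipace2d", cfg)


def find_anchors_disco(
    ref: PeakTable,
    aln: PeakTable,
    nb: NeighborhoodConfig = NeighborhoodConfig(),
    sim: SimilarityConfig = SimilarityConfig(),
) -> AnchorSet:
    """Top spectral similarity within the nearest-neighbour discrimination rule.

    Both tables are z-scored on their own statistics; for each reference
    peak only the nearest ``fraction`` of the aligned table competes,
    and the most similar candidate at or above the threshold wins.
    """
    if len(ref) == 0 or len(aln) == 0:
        return AnchorSet((), "disco", (nb, sim))
    zr = zscore_times(ref)
    za = zscore_times(aln)
    sim_fn = _pair_sim_fn(ref, aln, sim)
    candidates: list[AnchorPair] = []
    for i, p in enumerate(ref):
        best_j = -1
        best_s = -1.0
        for j in candidate_neighbors(zr[i], za, nb):
            s = sim_fn(i, j)
            if s < sim.threshold:
                continue
            if s > best_s:
                best_s = s
                best_j = j
        if best_j >= 0:
            candidates.append(AnchorPair(i, best_j, similarity=best_s, score=best_s))
    return AnchorSet(tuple(_resolve_one_to_one(candidates, ref, aln)), "disco", (nb, sim))


def find_anchors_msort(ref: PeakTable, aln: PeakTable, cfg: MSortConfig = MSortConfig()) -> AnchorSet:
    """Top spectral similarity inside a static raw-seconds search window."""
    sim_fn = _pair_sim_fn(ref, aln, cfg.similarity)
    candidates: list[AnchorPair] = []
    for i, p in enumerate(ref):
        best_j = -1
        best_s = -1.0
        for j, q in enumerate(aln):
            if abs(p.rt1 - q.rt1) > cfg.max_shift_1 or abs(p.rt2 - q.rt2) > cfg.max_shift_2:
                continue
            s = sim_fn(i, j)
            if s < cfg.similarity.threshold:
                continue
            if s > best_s:
                best_s = s
                best_j = j
        if best_j >= 0:
            candidates.append(AnchorPair(i, best_j, similarity=best_s, score=best_s))
    return AnchorSet(tuple(_resolve_one_to_one(candidates, ref, aln)), "msort", cfg)


def find_anchors_pam(ref: PeakTable, aln: PeakTable, cfg: PAMConfig = PAMConfig()) -> AnchorSet:
    """Exhaustive pairing under the weighted distance/similarity score.

    Every reference/aligned pair is considered. The spectral gate is
    evaluated first and a failing pair short-circuits: its distance is
    never computed. Matching is greedy one-to-one by descending score.
    """
    if len(ref) == 0 or len(aln) == 0:
        return AnchorSet((), "pam", cfg)
    zr = zscore_times(ref)
    za = zscore_times(aln)
    sim_fn = _pair_sim_fn(ref, aln, cfg.similarity)
    candidates: list[AnchorPair] = []
    for i, p in enumerate(ref):
        for j, q in enumerate(aln):
            s = sim_fn(i, j)
            if s < cfg.similarity.threshold:
                continue  # short-circuit: skip the distance computation
            d = peak_distance(zr[i], za[j], cfg.distance)
            candidates.append(AnchorPair(i, j, similarity=s, score=pam_match_score(d, s, cfg.w)))
    return AnchorSet(tuple(_resolve_one_to_one(candidates, ref, aln)), "pam", cfg)


def find_anchors_tntda(
    ref: PeakTable,
    aln: PeakTable,
    nb: NeighborhoodConfig = NeighborhoodConfig(distance="canberra"),
    pam: PAMConfig = PAMConfig(w=0.4),
) -> AnchorSet:
    """Neighbourhood discrimination rule plus weighted selection rule.

    Retention times are z-scored; for each reference peak the nearest
    ``fraction`` of aligned peaks are screened through the spectral
    gate, and the survivor with the highest weighted match score
    w/(1+D) + (1-w) S becomes the candidate match. With w = 0 and the
    Euclidean metric this reduces exactly to the top-similarity
    neighbourhood rule.
    """
    if len(ref) == 0 or len(aln) == 0:
        return AnchorSet((), "tntda", (nb, pam))
    zr = zscore_times(ref)
    za = zscore_times(aln)
    sim_fn = _pair_sim_fn(ref, aln, pam.similarity)
    threshold = pam.similarity.threshold
    candidates: list[AnchorPair] = []
    for i, p in enumerate(ref):
        best_j = -1
        best_m = -1.0
        best_s = 0.0
        for j in candidate_neighbors(zr[i], za, nb):
            s = sim_fn(i, j)
            if s < threshold:
                continue
            d = peak_distance(zr[i], za[j], nb.distance)
            m = pam_match_score(d, s, pam.w)
            if m > best_m:
                best_m = m
                best_j = j
                best_s = s
        if best_j >= 0:
            candidates.append(AnchorPair(i, best_j, similarity=best_s, score=best_m))
    return AnchorSet(tuple(_resolve_one_to_one(candidates, ref, aln)), "tntda", (nb, pam))


def smith_waterman_anchors(
    ref: PeakTable,
    aln: PeakTable,
    cfg: SmithWatermanConfig = SmithWatermanConfig(),
) -> AnchorSet:
    """Local alignment of the two elution orders.

    Peaks are sorted by total elution time; cell (i, j) of the scoring
    matrix treats the pair as a "match" when its spectral similarity
    reaches the threshold, otherwise a "mismatch", with the usual local
    recurrence max(0, diag + match/mismatch, up + gap, left + gap). The
    traceback starts at the global maximum and stops at a zero cell;
    diagonal steps where the match rule held become anchors.
    """
    n, m = len(ref), len(aln)
    if n == 0 or m == 0:
        return AnchorSet((), "smith_waterman", cfg)
    ref_order = sorted(range(n), key=lambda i: (ref[i].total_rt, i))
    aln_order = sorted(range(m), key=lambda j: (aln[j].total_rt, j))

    sim_fn = _pair_sim_fn(ref, aln, cfg.similarity)
    sims = np.empty((n, m), dtype=np.float64)
    for a, i in enumerate(ref_order):
        for b, j in enumerate(aln_order):
            sims[a, b] = sim_fn(i, j)
    matched = sims >= cfg.similarity.threshold

    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    move = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up, 3 left
    for a in range(1, n + 1):
        for b in range(1, m + 1):
            sub = cfg.match if matched[a - 1, b - 1] else cfg.mismatch
            options = (
                (H[a - 1, b - 1] + sub, 1),
                (H[a - 1, b] + cfg.gap, 2),
                (H[a, b - 1] + cfg.gap, 3),
            )
            best, mv = max(options, key=lambda t: t[0])
            if best <= 0.0:
                H[a, b] = 0.0
                move[a, b] = 0
            else:
                H[a, b] = best
                move[a, b] = mv

    a, b = np.unravel_index(int(H.argmax()), H.shape)
    pairs: list[AnchorPair] = []
    while H[a, b] > 0.0:
        mv = move[a, b]
        if mv == 1:
            if matched[a - 1, b - 1]:
                i, j = ref_order[a - 1], aln_order[b - 1]
                pairs.append(
                    AnchorPair(i, j, similarity=float(sims[a - 1, b - 1]), score=float(H[a, b]))
                )
            a, b = a - 1, b - 1
        elif mv == 2:
            a -= 1
        else:
            b -= 1
    pairs.sort(key=lambda p: p.ref_index)
    return AnchorSet(tuple(pairs), "smith_waterman", cfg)


# ---------------------------------------------------------------------------
# dispatch

ALGORITHMS = ("bipace2d", "disco", "msort", "pam", "tntda", "smith_waterman")


def find_anchors(algorithm: str, ref: PeakTable, aln: PeakTable, config=None) -> AnchorSet:
    """Run one algorithm by name with its config (defaults when None).

    For "disco" the config is a (NeighborhoodConfig, SimilarityConfig)
    pair and for "tntda" a (NeighborhoodConfig, PAMConfig) pair; the
    remaining algorithms take their own dataclass.
    """
    if algorithm == "bipace2d":
        return find_anchors_bipace(ref, aln, config or BiPACEConfig())
    if algorithm == "disco":
        nb, sim = config or (NeighborhoodConfig(), SimilarityConfig())
        return find_anchors_disco(ref, aln, nb, sim)
    if algorithm == "msort":
        return find_anchors_msort(ref, aln, config or MSortConfig())
    if algorithm == "pam":
        return find_anchors_pam(ref, aln, config or PAMConfig())
    if algorithm == "tntda":
        nb, pam = config or (NeighborhoodConfig(distance="canberra"), PAMConfig(w=0.4))
        return find_anchors_tntda(ref, aln, nb, pam)
    if algorithm == "smith_waterman":
        return smith_waterman_anchors(ref, aln, config or SmithWatermanConfig())
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
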