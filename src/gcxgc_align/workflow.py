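"""The alignment workflow for one chromatogram pair or a whole dataset.

Each aligned sample goes through the same six steps against the fixed
reference: find anchor peaks, check the elution order, export the
anchor points, fit and apply the retention-time-shift correction,
export the peak map, export the time-corrected chromatogram. The
correction is fitted per dimension independently, through the anchors
only, either as one global least-squares line or as a piecewise-linear
interpolation through the anchor knots (the default: exact at anchors
and tolerant of drift that turns nonlinear late in the temperature
program).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .anchors import AnchorSet, find_anchors
from .evaluation import KSResult, ks_per_dimension
from .peaks import Peak, PeakTable, PeakTableError, ValidationError

__all__ = [
    "WarpModel",
    "AlignmentResult",
    "ExclusionRegion",
    "ZeroAnchorsError",
    "check_elution_order",
    "build_warp",
    "apply_warp",
    "filter_exclusion_regions",
    "kovats_index_transform",
    "align_pair",
    "align_dataset",
    "summarize_results",
]

log = logging.getLogger(__name__)

FIT_KINDS = ("global_linear", "piecewise_linear")


class ZeroAnchorsError(PeakTableError):
    """No anchors survived: the warp cannot be fitted."""


@dataclass(frozen=True)
class _DimMap:
    """Monotone 1-D time map: one global line or a piecewise-linear spline.

    For the piecewise kind the knots are (aligned RT, reference RT)
    anchor pairs; outside the knot range the outermost segment is
    extended linearly. A single knot degenerates to a constant offset.
    """

    kind: str  # "linear" | "piecewise"
    a: float = 1.0
    b: float = 0.0
    knots_x: np.ndarray | None = None
    knots_y: np.ndarray | None = None

    def __call__(self, x):
        x = np.asarray(x, dtype=np.float64)
        if self.kind == "linear":
            return self.a * x + self.b
        kx, ky = self.knots_x, self.knots_y
        if len(kx) == 1:
            return x + (ky[0] - kx[0])
        y = np.interp(x, kx, ky)
        lo = x < kx[0]
        hi = x > kx[-1]
        if np.any(lo):
            s = (ky[1] - ky[0]) / (kx[1] - kx[0])
            y = np.where(lo, ky[0] + s * (x - kx[0]), y)
        if np.any(hi):
            s = (ky[-1] - ky[-2]) / (kx[-1] - kx[-2])
            y = np.where(hi, ky[-1] + s * (x - kx[-1]), y)
        return y


@dataclass(frozen=True)
class WarpModel:
    """Per-dimension monotone corrections mapping aligned RTs onto the reference axis."""

    dim1_map: _DimMap
    dim2_map: _DimMap
    fit_kind: str

    def coefficients(self, dim: int) -> tuple[float, float]:
        """(slope, intercept) of a global-linear dimension map."""
        m = (self.dim1_map, self.dim2_map)[dim - 1]
        if m.kind != "linear":
            raise ValidationError("coefficients are defined for global_linear fits only")
        return m.a, m.b


@dataclass(frozen=True)
class ExclusionRegion:
    """Closed rectangle in (rt1, rt2) to drop, e.g. a column-bleed band."""

    rt1_min: float
    rt1_max: float
    rt2_min: float
    rt2_max: float

    def __post_init__(self) -> None:
        if self.rt1_min > self.rt1_max or self.rt2_min > self.rt2_max:
            raise ValidationError("exclusion region bounds must satisfy lower <= upper")

    def contains(self, peak: Peak) -> bool:
        return (
            self.rt1_min <= peak.rt1 <= self.rt1_max
            and self.rt2_min <= peak.rt2 <= self.rt2_max
        )


@dataclass(frozen=True)
class AlignmentResult:
    """Everything one pair alignment produced."""

    reference: PeakTable
    aligned: PeakTable
    corrected: PeakTable
    anchors: AnchorSet  # post elution-order check
    warp: WarpModel
    ks_before: KSResult
    ks_after: KSResult
    n_anchors_raw: int  # before the elution-order check


def check_elution_order(anchors: AnchorSet, ref: PeakTable, aln: PeakTable) -> AnchorSet:
    """Drop anchors that violate the common elution order.

    Consistency is judged on total elution time (rt1 + rt2): for any two
    retained anchors the reference totals and the aligned totals must
    order the same way, strictly. The largest consistent subset is kept
    (a longest-strictly-increasing-subsequence computation — it removes
    the fewest anchors); removed pairs are reported in the log.
    """
    pairs = list(anchors.pairs)
    if len(pairs) <= 1:
        return anchors
    ref_tot = {p.ref_index: ref[p.ref_index].total_rt for p in pairs}
    aln_tot = {p.ref_index: aln[p.aln_index].total_rt for p in pairs}
    # Sorting aligned totals descending within a ref-total tie makes a
    # strictly-increasing subsequence reject ref-total ties altogether.
    order = sorted(pairs, key=lambda p: (ref_tot[p.ref_index], -aln_tot[p.ref_index]))
    seq = [aln_tot[p.ref_index] for p in order]
    n = len(seq)
    length = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if seq[j] < seq[i] and length[j] + 1 > length[i]:
                length[i] = length[j] + 1
                prev[i] = j
    end = int(np.argmax(length))
    keep_pos = []
    while end != -1:
        keep_pos.append(end)
        end = prev[end]
    kept = {order[i].ref_index for i in keep_pos}
    retained = tuple(p for p in pairs if p.ref_index in kept)
    removed = [p for p in pairs if p.ref_index not in kept]
    if removed:
        log.info(
            "elution-order check removed %d of %d anchors: %s",
            len(removed),
            len(pairs),
            [(p.ref_index, p.aln_index) for p in removed],
        )
    return AnchorSet(retained, anchors.algorithm, anchors.config)


def _knots(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort knots by aligned RT, averaging duplicates."""
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    ux, inv = np.unique(x, return_inverse=True)
    uy = np.zeros_like(ux)
    counts = np.zeros_like(ux)
    np.add.at(uy, inv, y)
    np.add.at(counts, inv, 1)
    return ux, uy / counts


def build_warp(
    anchors: AnchorSet,
    ref: PeakTable,
    aln: PeakTable,
    fit_kind: str = "piecewise_linear",
) -> WarpModel:
    """Fit the per-dimension time correction through the anchors.

    global_linear fits one least-squares line rt_ref ~ a*rt_aln + b per
    dimension (needs >= 2 anchors at distinct aligned RTs);
    piecewise_linear interpolates through the anchor knots with linear
    extrapolation from the outermost segment and works from one anchor
    up (a single anchor gives a constant offset).
    """
    if fit_kind not in FIT_KINDS:
        raise ValueError(f"fit_kind must be one of {FIT_KINDS}")
    if len(anchors) == 0:
        raise ZeroAnchorsError(
            "cannot fit a time correction from zero anchors; relax the similarity "
            "threshold or widen the search window/tolerances"
        )
    maps = []
    for dim in (1, 2):
        x = np.array([(aln[p.aln_index].rt1, aln[p.aln_index].rt2)[dim - 1] for p in anchors])
        y = np.array([(ref[p.ref_index].rt1, ref[p.ref_index].rt2)[dim - 1] for p in anchors])
        if fit_kind == "global_linear":
            if len(anchors) < 2 or np.ptp(x) == 0:
                raise ZeroAnchorsError(
                    f"global_linear needs >= 2 anchors at distinct aligned RTs in dimension {dim}"
                )
            a, b = np.polyfit(x, y, 1)
            maps.append(_DimMap(kind="linear", a=float(a), b=float(b)))
        else:
            kx, ky = _knots(x, y)
            maps.append(_DimMap(kind="piecewise", knots_x=kx, knots_y=ky))
    return WarpModel(dim1_map=maps[0], dim2_map=maps[1], fit_kind=fit_kind)


def apply_warp(table: PeakTable, warp: WarpModel) -> PeakTable:
    """Map every peak's retention times; spectra, labels and order untouched.

    A corrected time that falls below zero is clamped to 0 with a
    warning rather than dropping the peak.
    """
    if len(table) == 0:
        return table
    new1 = np.atleast_1d(warp.dim1_map(table.rt1()))
    new2 = np.atleast_1d(warp.dim2_map(table.rt2()))
    n_neg = int(np.sum(new1 < 0) + np.sum(new2 < 0))
    if n_neg:
        log.warning("%s: clamped %d negative corrected retention times to 0", table.sample_id, n_neg)
    peaks = [
        Peak(rt1=max(0.0, float(t1)), rt2=max(0.0, float(t2)), spectrum=p.spectrum, label=p.label)
        for p, t1, t2 in zip(table, new1, new2)
    ]
    return table.with_peaks(peaks)


def filter_exclusion_regions(table: PeakTable, regions: Sequence[ExclusionRegion]) -> PeakTable:
    """Drop peaks inside any exclusion rectangle (closed intervals)."""
    if not regions:
        return table
    kept = [p for p in table if not any(r.contains(p) for r in regions)]
    removed = len(table) - len(kept)
    if removed:
        log.info("%s: excluded %d peak(s) inside %d region(s)", table.sample_id, removed, len(regions))
    return table.with_peaks(kept)


def _ladder_interp(x: np.ndarray, rts: np.ndarray, idxs: np.ndarray) -> np.ndarray:
    """Linear interpolation through a ladder with end-segment extrapolation."""
    seg = np.clip(np.searchsorted(rts, x, side="right") - 1, 0, len(rts) - 2)
    x0, x1 = rts[seg], rts[seg + 1]
    y0, y1 = idxs[seg], idxs[seg + 1]
    return y0 + (x - x0) * (y1 - y0) / (x1 - x0)


def kovats_index_transform(
    table: PeakTable,
    ladder1: Sequence[tuple[float, float]],
    ladder2: Sequence[tuple[float, float]],
) -> np.ndarray:
    """Retention (Kovats) indices per peak from per-dimension ladders.

    Each ladder is a strictly increasing list of (retention time s,
    retention index) reference points — typically an n-alkane series
    under a linear temperature program. Indices are linearly
    interpolated between bracketing ladder points and linearly
    extrapolated outside; expressing both dimensions on the index scale
    aligns runs without any other manipulation. Returns an (n, 2)
    array of (RI1, RI2).
    """
    out = np.empty((len(table), 2), dtype=np.float64)
    for d, (ladder, rt) in enumerate(((ladder1, table.rt1()), (ladder2, table.rt2()))):
        pts = np.asarray(ladder, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
            raise ValidationError(f"dimension {d + 1}: ladder needs >= 2 (rt, index) pairs")
        rts, idxs = pts[:, 0], pts[:, 1]
        if np.any(np.diff(rts) <= 0) or np.any(np.diff(idxs) <= 0):
            raise ValidationError(f"dimension {d + 1}: ladder must be strictly increasing")
        out[:, d] = _ladder_interp(rt, rts, idxs)
    return out


def align_pair(
    ref: PeakTable,
    aln: PeakTable,
    algorithm: str = "tntda",
    config=None,
    fit_kind: str = "piecewise_linear",
    exclusion_regions: Sequence[ExclusionRegion] = (),
) -> AlignmentResult:
    """Run the full six-step workflow for one reference/aligned pair.

    Exclusion regions (column-bleed bands) are filtered from both tables
    first; K-S diagnostics per dimension are recorded before and after
    the correction. Raises :class:`ZeroAnchorsError` when no anchor
    survives.
    """
    ref_f = filter_exclusion_regions(ref, exclusion_regions)
    aln_f = filter_exclusion_regions(aln, exclusion_regions)
    raw = find_anchors(algorithm, ref_f, aln_f, config)
    anchors = check_elution_order(raw, ref_f, aln_f)
    log.info(
        "%s vs %s [%s]: %d anchors found, %d after elution-order check",
        ref_f.sample_id,
        aln_f.sample_id,
        algorithm,
        len(raw),
        len(anchors),
    )
    warp = build_warp(anchors, ref_f, aln_f, fit_kind)
    corrected = apply_warp(aln_f, warp)
    return AlignmentResult(
        reference=ref_f,
        aligned=aln_f,
        corrected=corrected,
        anchors=anchors,
        warp=warp,
        ks_before=ks_per_dimension(ref_f, aln_f),
        ks_after=ks_per_dimension(ref_f, corrected),
        n_anchors_raw=len(raw),
    )


def align_dataset(
    ref_id: str,
    tables: Sequence[PeakTable],
    algorithm: str = "tntda",
    config=None,
    fit_kind: str = "piecewise_linear",
    exclusion_regions: Sequence[ExclusionRegion] = (),
) -> list[AlignmentResult]:
    """Align every other table, one by one, to the fixed reference."""
    ids = [t.sample_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids in dataset")
    by_id = {t.sample_id: t for t in tables}
    if ref_id not in by_id:
        raise ValidationError(f"reference sample {ref_id!r} not found among {ids}")
    ref = by_id[ref_id]
    return [
        align_pair(ref, t, algorithm, config, fit_kind, exclusion_regions)
        for t in tables
        if t.sample_id != ref_id
    ]


def summarize_results(results: Sequence[AlignmentResult]) -> "pd.DataFrame":  # noqa: F821
    """One summary row per aligned sample (anchor counts, K-S before/after)."""
    import pandas as pd

    rows = [
        {
            "sample_id": r.aligned.sample_id,
            "algorithm": r.anchors.algorithm,
            "n_anchors_raw": r.n_anchors_raw,
            "n_anchors": len(r.anchors),
            "ks1_before": r.ks_before.d1,
            "ks2_before": r.ks_before.d2,
            "ks1_after": r.ks_after.d1,
            "ks2_after": r.ks_after.d2,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
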