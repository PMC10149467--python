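"""Reading and writing peak tables and alignment outputs.

The input format mirrors what peak-detection software exports: a
tab-separated text table with a header row, one detected peak per row,
carrying both retention times (s) and the spectrum encoded as a single
string of ``m/z:intensity`` tokens. Vendors vary in their exact header
strings and separators, so the dialect is configurable.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

from .peaks import Peak, PeakTable, PeakTableError, Spectrum, ValidationError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for typing only
    from .workflow import AlignmentResult

__all__ = [
    "TableDialect",
    "SpectrumParseError",
    "SchemaError",
    "parse_spectrum_string",
    "format_spectrum_string",
    "read_peak_table",
    "write_peak_table",
    "write_outputs",
    "ANCHOR_COLUMNS",
    "PEAK_MAP_COLUMNS",
]


class SpectrumParseError(PeakTableError):
    """A spectrum string token could not be parsed."""


class SchemaError(PeakTableError):
    """The file header does not contain a required column."""


@dataclass(frozen=True)
class TableDialect:
    """CSV dialect of an exported peak table.

    field_sep    column separator (tab, per the export convention)
    pair_sep     separator inside an ``m/z:intensity`` token
    rt1_col etc. header names of the three required columns
    """

    field_sep: str = "\t"
    pair_sep: str = ":"
    rt1_col: str = "1st Dimension Time (s)"
    rt2_col: str = "2nd Dimension Time (s)"
    spectrum_col: str = "Spectra"
    label_col: str | None = "Name"

    @property
    def required(self) -> tuple[str, str, str]:
        return (self.rt1_col, self.rt2_col, self.spectrum_col)


def parse_spectrum_string(text: str, pair_sep: str = ":", *, row: int | None = None) -> Spectrum:
    """Parse a whitespace-separated string of ``m/z:intensity`` tokens.

    Duplicate m/z keys are summed (a unit-mass export may bin two
    fragments onto one nominal mass). Malformed tokens raise
    :class:`SpectrumParseError` naming the row and the offending token.
    """
    where = "" if row is None else f" (row {row})"
    intensities: dict[int, float] = {}
    for token in text.split():
        head, sep, tail = token.partition(pair_sep)
        if not sep:
            raise SpectrumParseError(
                f"token {token!r}{where} lacks the pair separator {pair_sep!r}"
            )
        try:
            mz = int(head)
            inten = float(tail)
        except ValueError as exc:
            raise SpectrumParseError(f"non-numeric token {token!r}{where}") from exc
        intensities[mz] = intensities.get(mz, 0.0) + inten
    return Spectrum(intensities)


def format_spectrum_string(s: Spectrum, pair_sep: str = ":") -> str:
    """Inverse of :func:`parse_spectrum_string` (m/z ascending)."""
    return " ".join(f"{mz}{pair_sep}{inten:.10g}" for mz, inten in s.items())


def read_peak_table(
    path: str | os.PathLike,
    dialect: TableDialect = TableDialect(),
    sample_id: str | None = None,
) -> PeakTable:
    """Read one exported peak table; row order is preserved.

    ``sample_id`` defaults to the file stem. Missing required columns
    raise :class:`SchemaError`; a negative retention time raises
    :class:`ValidationError` naming the data row (1-based, excluding the
    header).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.field_sep, dtype=str, keep_default_na=False)
    missing = [c for c in dialect.required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}; found {list(df.columns)}")
    has_label = dialect.label_col is not None and dialect.label_col in df.columns

    peaks: list[Peak] = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, rec))
        try:
            rt1 = float(row[dialect.rt1_col])
            rt2 = float(row[dialect.rt2_col])
        except ValueError as exc:
            raise ValidationError(f"{path.name} row {i}: non-numeric retention time") from exc
        if rt1 < 0 or rt2 < 0:
            raise ValidationError(f"{path.name} row {i}: negative retention time ({rt1}, {rt2})")
        spectrum = parse_spectrum_string(row[dialect.spectrum_col], dialect.pair_sep, row=i)
        label = row[dialect.label_col] or None if has_label else None
        peaks.append(Peak(rt1=rt1, rt2=rt2, spectrum=spectrum, label=label))
    return PeakTable(sample_id=sample_id or path.stem, peaks=tuple(peaks))


def write_peak_table(
    table: PeakTable,
    path: str | os.PathLike,
    dialect: TableDialect = TableDialect(),
) -> None:
    """Write a peak table in the input dialect (RTs to 1e-6 s)."""
    cols: dict[str, list] = {
        dialect.rt1_col: [f"{p.rt1:.6f}" for p in table],
        dialect.rt2_col: [f"{p.rt2:.6f}" for p in table],
        dialect.spectrum_col: [format_spectrum_string(p.spectrum, dialect.pair_sep) for p in table],
    }
    if dialect.label_col is not None and any(p.label for p in table):
        cols[dialect.label_col] = [p.label or "" for p in table]
    pd.DataFrame(cols).to_csv(path, sep=dialect.field_sep, index=False)


ANCHOR_COLUMNS = (
    "ref_index",
    "aln_index",
    "ref_rt1",
    "ref_rt2",
    "aln_rt1",
    "aln_rt2",
    "similarity",
    "score",
)

PEAK_MAP_COLUMNS = (
    "ref_index",
    "aln_index",
    "ref_rt1",
    "ref_rt2",
    "aln_rt1",
    "aln_rt2",
    "corrected_rt1",
    "corrected_rt2",
    "similarity",
)


def write_outputs(
    result: "AlignmentResult",
    out_dir: str | os.PathLike,
    dialect: TableDialect = TableDialect(),
) -> dict[str, Path]:
    """Export the alignment products of one reference/aligned pair.

    Writes three files into ``out_dir`` and returns their paths:

    * ``anchor_points.csv`` — one row per anchor surviving the elution
      check, with both raw coordinates, the spectral similarity and the
      algorithm's selection score (columns :data:`ANCHOR_COLUMNS`);
    * ``peak_map.csv`` — every matched peak with its corrected times
      (columns :data:`PEAK_MAP_COLUMNS`);
    * ``corrected_<sample>.csv`` — the time-corrected peak table in the
      input dialect.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref, aln, corr = result.reference, result.aligned, result.corrected

    anchor_rows = [
        {
            "ref_index": p.ref_index,
            "aln_index": p.aln_index,
            "ref_rt1": ref[p.ref_index].rt1,
            "ref_rt2": ref[p.ref_index].rt2,
            "aln_rt1": aln[p.aln_index].rt1,
            "aln_rt2": aln[p.aln_index].rt2,
            "similarity": p.similarity,
            "score": p.score,
        }
        for p in result.anchors.pairs
    ]
    anchors_path = out / "anchor_points.csv"
    pd.DataFrame(anchor_rows, columns=list(ANCHOR_COLUMNS)).to_csv(anchors_path, sep="\t", index=False)

    map_rows = [
        {
            "ref_index": p.ref_index,
            "aln_index": p.aln_index,
            "ref_rt1": ref[p.ref_index].rt1,
            "ref_rt2": ref[p.ref_index].rt2,
            "aln_rt1": aln[p.aln_index].rt1,
            "aln_rt2": aln[p.aln_index].rt2,
            "corrected_rt1": corr[p.aln_index].rt1,
            "corrected_rt2": corr[p.aln_index].rt2,
            "similarity": p.similarity,
        }
        for p in result.anchors.pairs
    ]
    map_path = out / "peak_map.csv"
    pd.DataFrame(map_rows, columns=list(PEAK_MAP_COLUMNS)).to_csv(map_path, sep="\t", index=False)

    corrected_path = out / f"corrected_{corr.sample_id}.csv"
    write_peak_table(corr, corrected_path, dialect)
    return {"anchors": anchors_path, "peak_map": map_path, "corrected": corrected_path}
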