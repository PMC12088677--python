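"""Plain-text I/O for peak lists, relaxation intensity tables, and results.

All tabular I/O is UTF-8, tab-delimited, with "." as the decimal separator.
Residue numbering is 1-based full-length GeoCas9 numbering throughout; the
GeoRec construct spans residues 90-456 and any construct offset is metadata,
never applied silently.

Two peak-list dialects are supported:

``sparky``
    Assignment strings of the form ``<AA><number>N-H`` (e.g. ``K267N-H``)
    followed by w1 (¹⁵N ppm), w2 (¹H ppm) and, optionally, an intensity
    column.  Unassigned rows (``?-?`` and friends) go to a skip list and are
    reported, never silently dropped.

``tsv``
    Header ``residue  aa  dH_ppm  dN_ppm  intensity  condition``.

Intensity tables are TSV with the header
``residue  field_MHz  axis_kind  axis_value  intensity  replicate`` where
``axis_kind`` is one of ``cpmg`` (νCPMG in Hz), ``t1``/``t2`` (delay in s)
or ``noe`` (axis_value 0 = reference, 1 = saturated).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ResidueKey",
    "PeakTable",
    "IntensitySeries",
    "ParseError",
    "read_peak_list",
    "write_peak_list",
    "read_intensity_table",
    "write_intensity_table",
    "read_results",
    "write_results",
]

AXIS_KINDS = ("cpmg", "t1", "t2", "noe")

PEAK_COLUMNS = ["residue", "aa", "dH_ppm", "dN_ppm", "intensity", "condition"]
INTENSITY_COLUMNS = ["residue", "field_MHz", "axis_kind", "axis_value",
                     "intensity", "replicate"]

_SPARKY_ASSIGNMENT = re.compile(r"^([A-Z])(\d+)N-H$")


class ParseError(ValueError):
    """A table or peak list could not be parsed."""


@dataclass(frozen=True, order=True)
class ResidueKey:
    """A residue in full-length GeoCas9 numbering, with optional aa code."""

    number: int
    aa: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.number < 1:
            raise ValueError(f"residue number must be >= 1, got {self.number}")

    def __str__(self) -> str:
        return f"{self.aa or 'X'}{self.number}"


@dataclass
class PeakTable:
    """Peak records for one or more conditions.

    ``data`` has columns residue, aa, dH_ppm, dN_ppm, intensity, condition;
    ``skipped`` lists (line number, text) of unparseable assignment rows.
    """

    data: pd.DataFrame
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        dup = self.data.duplicated(subset=["residue", "condition"])
        if dup.any():
            bad = self.data.loc[dup, "residue"].tolist()
            raise ParseError(f"duplicate residue(s) within one condition: {bad}")
        for col in ("dH_ppm", "dN_ppm"):
            vals = self.data[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ParseError(f"non-finite values in column {col}")

    def __len__(self) -> int:
        return len(self.data)

    def condition(self, label: str) -> pd.DataFrame:
        return self.data[self.data["condition"] == label].set_index("residue")


@dataclass
class IntensitySeries:
    """Intensities along one relaxation axis for a single residue and field.

    ``points`` has columns axis_value, intensity, replicate.  Duplicate axis
    values are legitimate (replicate spectra for error estimation) and are
    distinguished by the replicate index.
    """

    residue: ResidueKey
    field_mhz: float
    axis_kind: str
    points: pd.DataFrame

    def __post_init__(self) -> None:
        if self.axis_kind not in AXIS_KINDS:
            raise ValueError(f"axis_kind must be one of {AXIS_KINDS}")
        self.points = self.points.astype({"axis_value": float,
                                          "intensity": float,
                                          "replicate": int})
        inten = self.points["intensity"].to_numpy(dtype=float)
        if self.axis_kind == "noe":
            ref = self.points[self.points["axis_value"] == 0.0]
            if ref.empty:
                raise ParseError(
                    f"residue {self.residue}: NOE series lacks a reference "
                    "(axis_value 0) point")
            if (ref["intensity"] <= 0).any():
                raise ParseError(
                    f"residue {self.residue}: non-positive NOE reference intensity")
        else:
            if np.any(inten <= 0):
                raise ParseError(
                    f"residue {self.residue}: non-positive intensity in "
                    f"{self.axis_kind} series")
            if not (self.points["axis_value"] == 0.0).any():
                raise ParseError(
                    f"residue {self.residue}: {self.axis_kind} series lacks a "
                    "reference point (axis value 0)")

    @property
    def duplicated_axis_values(self) -> list[float]:
        counts = self.points["axis_value"].value_counts()
        return sorted(counts.index[counts > 1].tolist())


def _parse_sparky_line(line_no: int, tokens: list[str]) -> tuple:
    m = _SPARKY_ASSIGNMENT.match(tokens[0])
    if m is None:
        return None
    if len(tokens) < 3:
        raise ParseError(f"line {line_no}: expected w1/w2 after assignment")
    try:
        w1 = float(tokens[1])  # ¹⁵N ppm
        w2 = float(tokens[2])  # ¹H ppm
        inten = float(tokens[3]) if len(tokens) > 3 else np.nan
    except ValueError as exc:
        raise ParseError(f"line {line_no}: {exc}") from exc
    return int(m.group(2)), m.group(1), w2, w1, inten


def read_peak_list(path: str | Path, dialect: str = "sparky",
                   condition: str | None = None) -> PeakTable:
    """Read a peak list in ``sparky`` or ``tsv`` dialect.

    For the sparky dialect every data row must carry an assignment of the
    form ``<AA><number>N-H``; rows whose assignment does not match (e.g.
    ``?-?``) are collected in the returned table's ``skipped`` list.
    ``condition`` defaults to the file stem.
    """
    path = Path(path)
    if dialect not in ("sparky", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    label = condition if condition is not None else path.stem

    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"condition": str})
        missing = set(PEAK_COLUMNS) - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        return PeakTable(df[PEAK_COLUMNS].copy())

    records: list[tuple] = []
    skipped: list[tuple[int, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.lower().startswith("assignment"):
                continue
            tokens = line.split()
            parsed = _parse_sparky_line(line_no, tokens)
            if parsed is None:
                skipped.append((line_no, line))
                continue
            records.append(parsed + (label,))
    df = pd.DataFrame(records, columns=PEAK_COLUMNS)
    return PeakTable(df, skipped=skipped)


def write_peak_list(table: PeakTable, path: str | Path) -> None:
    """Write a PeakTable in the tsv dialect (lossless)."""
    table.data[PEAK_COLUMNS].to_csv(path, sep="\t", index=False,
                                    encoding="utf-8")


def read_intensity_table(path: str | Path) -> list[IntensitySeries]:
    """Read a relaxation intensity table into one series per
    (residue, field, axis kind), preserving replicate points."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(INTENSITY_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad_kind = set(df["axis_kind"].unique()) - set(AXIS_KINDS)
    if bad_kind:
        raise ParseError(f"{path}: unknown axis_kind values {sorted(bad_kind)}")

    out: list[IntensitySeries] = []
    for (res, field_mhz, kind), grp in df.groupby(
            ["residue", "field_MHz", "axis_kind"], sort=True):
        pts = grp[["axis_value", "intensity", "replicate"]].reset_index(drop=True)
        out.append(IntensitySeries(ResidueKey(int(res)), float(field_mhz),
                                   str(kind), pts))
    return out


def write_intensity_table(series: list[IntensitySeries],
                          path: str | Path) -> None:
    rows = []
    for s in series:
        for _, p in s.points.iterrows():
            rows.append((s.residue.number, s.field_mhz, s.axis_kind,
                         p["axis_value"], p["intensity"], int(p["replicate"])))
    df = pd.DataFrame(rows, columns=INTENSITY_COLUMNS)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def write_results(table: pd.DataFrame, path: str | Path,
                  format: str = "tsv") -> None:
    """Write a result table losslessly as TSV or JSON records.

    Column order is preserved exactly as given; floats are written at full
    repr precision so a read-back reproduces them within 1e-12.
    """
    path = Path(path)
    if format == "tsv":
        table.to_csv(path, sep="\t", index=False, encoding="utf-8")
    elif format == "json":
        payload = {"columns": list(table.columns),
                   "records": table.to_dict(orient="records")}
        path.write_text(json.dumps(payload, indent=1, default=str),
                        encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_results(path: str | Path, format: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "tsv"
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    payload = json.loads(path.read_text(encoding="utf-8"))
    return pd.DataFrame(payload["records"], columns=payload["columns"])
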