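"""Reading and writing the tabular formats the pipeline touches.

Measurement/coefficient tables follow the two-sheet layout used for the
published per-seed data: a "Discrete measures" sheet (Sample, Seed, length,
width, thickness in cm, surface in cm^2) and a "Fourier coefficients" sheet
with 32 dorsal columns (suffix ``VD``) and 32 lateral columns (suffix
``VL``) named ``A/B/C/D`` + column number 1..8.  The stored columns are the
*retained* harmonics: by default column number ``h`` holds harmonic
``h + harmonic_offset`` of the normalized transform (offset 1, i.e. "A1VD"
is harmonic 2, the first harmonic being consumed by the normalization).

Outlines are read from plain x,y CSV or TPS landmark blocks.  All numeric
parsing is locale-independent (dot decimal separator).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .outline_ops import Outline

__all__ = [
    "SeedRecord",
    "Dataset",
    "COEFF_COLUMNS",
    "SIZE_COLUMNS",
    "STATUSES",
    "FormatError",
    "IntegrityError",
    "ParseError",
    "load_bundled_metadata",
    "read_measurement_table",
    "read_outline_file",
    "write_outline_file",
    "write_results_table",
    "write_measurement_table",
]

SIZE_COLUMNS = ["length", "width", "thickness", "surface"]
STATUSES = ("cultivated", "feral", "uncultivated_unknown", "wild_reference")

#: S1-style coefficient column names, dorsal block first, in the exact order
#: of the 64-entry retained shape vector (A,B,C,D within each harmonic).
COEFF_COLUMNS = [
    f"{letter}{h}{view}"
    for view in ("VD", "VL")
    for h in range(1, 9)
    for letter in "ABCD"
]


class FormatError(ValueError):
    """A mandatory column or sheet is missing."""


class IntegrityError(ValueError):
    """Duplicate identifiers or metadata/record mismatch."""


class ParseError(ValueError):
    """A cell could not be parsed as a number."""


@dataclass
class SeedRecord:
    """One seed: identity, metadata, size vector and shape coefficients."""

    seed_id: str
    sample_id: str
    species: str
    accession: str
    status: str
    length: float | None = None
    width: float | None = None
    thickness: float | None = None
    surface: float | None = None
    dorsal_coeffs: np.ndarray | None = None
    lateral_coeffs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        for name in SIZE_COLUMNS:
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        for name in ("dorsal_coeffs", "lateral_coeffs"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (32,):
                    raise ValueError(f"{name} must have exactly 32 entries")
                setattr(self, name, v)


class Dataset:
    """An ordered collection of seed records plus per-sample metadata.

    Internally a pair of aligned DataFrames: ``measures`` (one row per seed,
    metadata joined in) and ``coeffs`` (seed_id-indexed 64-column shape
    table; rows may be absent for size-only seeds, which are flagged).
    """

    def __init__(self, measures: pd.DataFrame, coeffs: pd.DataFrame, metadata: pd.DataFrame):
        required = {"seed_id", "sample_id", "species", "status"}
        missing = required - set(measures.columns)
        if missing:
            raise FormatError(f"measures frame missing columns: {sorted(missing)}")
        if measures["seed_id"].duplicated().any():
            dup = measures.loc[measures["seed_id"].duplicated(), "seed_id"].iloc[0]
            raise IntegrityError(f"duplicate seed_id {dup!r}")
        unknown = set(measures["sample_id"]) - set(metadata["sample_id"])
        if unknown:
            raise IntegrityError(f"sample ids missing from metadata: {sorted(unknown)[:5]}")
        self.measures = measures.reset_index(drop=True)
        self.coeffs = coeffs
        self.metadata = metadata.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.measures)

    @property
    def species(self) -> list[str]:
        return sorted(self.measures["species"].unique())

    @property
    def missing_coeff_seed_ids(self) -> list[str]:
        return [s for s in self.measures["seed_id"] if s not in self.coeffs.index]

    def seed_counts(self, by: str = "species") -> pd.Series:
        return self.measures.groupby(by).size()

    def subset(
        self,
        species: Iterable[str] | None = None,
        exclude_species: Iterable[str] | None = None,
        status: Iterable[str] | None = None,
        sample_ids: Iterable[str] | None = None,
    ) -> "Dataset":
        m = self.measures
        keep = pd.Series(True, index=m.index)
        if species is not None:
            keep &= m["species"].isin(list(species))
        if exclude_species is not None:
            keep &= ~m["species"].isin(list(exclude_species))
        if status is not None:
            keep &= m["status"].isin(list(status))
        if sample_ids is not None:
            keep &= m["sample_id"].isin(list(sample_ids))
        m = m[keep]
        c = self.coeffs.loc[self.coeffs.index.intersection(m["seed_id"])]
        return Dataset(m, c, self.metadata)

    def size_matrix(self) -> pd.DataFrame:
        """Seeds x 4 size parameters, seed_id-indexed (complete rows only)."""
        df = self.measures.set_index("seed_id")[SIZE_COLUMNS]
        return df.dropna()

    def shape_matrix(self) -> pd.DataFrame:
        """Seeds x 64 coefficients in measures order (seeds with coefficients)."""
        ids = [s for s in self.measures["seed_id"] if s in self.coeffs.index]
        return self.coeffs.loc[ids, COEFF_COLUMNS]

    def labels_for(self, index: pd.Index, column: str = "species") -> pd.Series:
        return self.measures.set_index("seed_id").loc[index, column]

    @property
    def records(self) -> list[SeedRecord]:
        out = []
        for _, row in self.measures.iterrows():
            sid = row["seed_id"]
            if sid in self.coeffs.index:
                c = self.coeffs.loc[sid, COEFF_COLUMNS].to_numpy(dtype=float)
                dors, lat = c[:32], c[32:]
            else:
                dors = lat = None
            out.append(
                SeedRecord(
                    seed_id=sid,
                    sample_id=row["sample_id"],
                    species=row["species"],
                    accession=row.get("accession", row["sample_id"]),
                    status=row["status"],
                    length=_none_if_nan(row.get("length")),
                    width=_none_if_nan(row.get("width")),
                    thickness=_none_if_nan(row.get("thickness")),
                    surface=_none_if_nan(row.get("surface")),
                    dorsal_coeffs=dors,
                    lateral_coeffs=lat,
                )
            )
        return out


def _none_if_nan(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


def load_bundled_metadata() -> pd.DataFrame:
    """Per-sample metadata shipped with the package: sample_id, species,
    status, role (cultivar/seedling/feral/uncultivated/wild), nominal seed
    count and origin for the 85 accessions of the reference panel."""
    with resources.files("seedmorph.data").joinpath("phoenix_samples.csv").open() as fh:
        return pd.read_csv(fh, dtype={"sample_id": str}, keep_default_na=False)


def _coerce_numeric(df: pd.DataFrame, columns: list[str], source: str) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{source}: non-numeric value {df[col].iloc[row]!r} at row {row + 2}, column {col!r}"
            )
        df[col] = coerced
    return df


def read_measurement_table(
    path,
    metadata_path=None,
    coeff_path=None,
    sheet_measures: str = "Discrete measures",
    sheet_coeffs: str = "Fourier coefficients",
    harmonic_offset: int = 1,
) -> Dataset:
    """Read a measurement/coefficient table into a :class:`Dataset`.

    ``path`` may be a two-sheet spreadsheet (.xlsx) or the measures CSV of a
    paired-CSV dialect, in which case ``coeff_path`` locates the coefficient
    CSV (optional; seeds then carry sizes only and are flagged).  Metadata
    (species/status per sample) comes from ``metadata_path`` or the bundled
    panel table.  ``harmonic_offset`` documents which harmonic column "1"
    stores (default: retained harmonic 2); it is carried through unchanged
    since the stored columns are already the retained set.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        try:
            meas = pd.read_excel(path, sheet_name=sheet_measures)
            coef = pd.read_excel(path, sheet_name=sheet_coeffs)
        except ValueError as exc:
            raise FormatError(f"missing sheet in {path.name}: {exc}") from exc
    else:
        meas = pd.read_csv(path)
        coef = pd.read_csv(coeff_path) if coeff_path is not None else None

    for col in ["Sample", "Seed"] + SIZE_COLUMNS:
        if col not in meas.columns:
            raise FormatError(f"measures table is missing mandatory column {col!r}")
    meas = _coerce_numeric(meas, SIZE_COLUMNS, "measures")
    if meas["Seed"].duplicated().any():
        dup = meas.loc[meas["Seed"].duplicated(), "Seed"].iloc[0]
        raise IntegrityError(f"duplicate seed_id {dup!r} in measures table")

    if metadata_path is None:
        metadata = load_bundled_metadata()
    else:
        metadata = pd.read_csv(metadata_path, dtype={"sample_id": str}, keep_default_na=False)
    for col in ("sample_id", "species", "status"):
        if col not in metadata.columns:
            raise FormatError(f"metadata is missing mandatory column {col!r}")

    measures = meas.rename(columns={"Sample": "sample_id", "Seed": "seed_id"})
    measures = measures.merge(
        metadata[[c for c in ("sample_id", "species", "status", "role") if c in metadata.columns]],
        on="sample_id",
        how="left",
    )
    if measures["species"].isna().any():
        missing = measures.loc[measures["species"].isna(), "sample_id"].unique()
        raise IntegrityError(f"samples absent from metadata: {list(missing)[:5]}")
    measures["accession"] = measures["sample_id"]

    if coef is not None and len(coef):
        for col in ["Seed"] + COEFF_COLUMNS:
            if col not in coef.columns:
                raise FormatError(f"coefficient table is missing mandatory column {col!r}")
        coef = _coerce_numeric(coef, COEFF_COLUMNS, "coefficients")
        if coef["Seed"].duplicated().any():
            raise IntegrityError("duplicate seed_id in coefficient table")
        coeffs = coef.set_index("Seed")[COEFF_COLUMNS]
        coeffs.index.name = "seed_id"
    else:
        coeffs = pd.DataFrame(columns=COEFF_COLUMNS, index=pd.Index([], name="seed_id"))
    ds = Dataset(measures, coeffs, metadata)
    ds.harmonic_offset = harmonic_offset
    return ds


_TPS_LM = re.compile(r"^\s*LM\s*=\s*(\d+)\s*$", re.IGNORECASE)


def read_outline_file(path, view: str | None = None) -> Outline:
    """Read a closed outline from an x,y CSV or a TPS landmark block."""
    path = Path(path)
    text = path.read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    pts: list[tuple[float, float]] = []
    if lines and _TPS_LM.match(lines[0]):
        n = int(_TPS_LM.match(lines[0]).group(1))
        for ln in lines[1 : 1 + n]:
            parts = ln.replace(",", " ").split()
            if len(parts) < 2:
                raise ParseError(f"{path.name}: malformed TPS coordinate line {ln!r}")
            pts.append((_parse_float(parts[0], path), _parse_float(parts[1], path)))
        if len(pts) != n:
            raise ParseError(f"{path.name}: TPS block declares {n} landmarks, found {len(pts)}")
    else:
        start = 1 if lines and not _looks_numeric(lines[0].split(",")[0]) else 0
        for ln in lines[start:]:
            parts = ln.split(",") if "," in ln else ln.split()
            if len(parts) < 2:
                raise ParseError(f"{path.name}: malformed coordinate line {ln!r}")
            pts.append((_parse_float(parts[0], path), _parse_float(parts[1], path)))
    arr = np.asarray(pts, dtype=float)
    if np.isnan(arr).any():
        raise ParseError(f"{path.name}: NaN coordinate")
    return Outline(points=arr, view=view)


def _looks_numeric(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _parse_float(s: str, path) -> float:
    try:
        return float(s)
    except ValueError as exc:
        raise ParseError(f"{Path(path).name}: cannot parse {s!r} as a number") from exc


def write_outline_file(outline: Outline, path) -> None:
    """Write an outline as TPS (``.tps``) or x,y CSV (anything else)."""
    path = Path(path)
    pts = outline.points
    if path.suffix.lower() == ".tps":
        lines = [f"LM={len(pts)}"] + [f"{x:.12g} {y:.12g}" for x, y in pts]
        path.write_text("\n".join(lines) + "\n")
    else:
        lines = ["x,y"] + [f"{x:.12g},{y:.12g}" for x, y in pts]
        path.write_text("\n".join(lines) + "\n")


def write_results_table(rows, path, index: bool = False) -> None:
    """Write result records (DataFrame, list of dicts or dataclasses) to CSV
    with enough digits that a read-back is value-identical to 12 significant
    digits."""
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows and hasattr(rows[0], "__dataclass_fields__"):
            rows = [vars(r) for r in rows]
        df = pd.DataFrame(rows)
    df.to_csv(path, index=index, float_format="%.12g")


def write_measurement_table(dataset: Dataset, path, coeff_path=None) -> None:
    """Emit a dataset in the two-sheet (.xlsx) or paired-CSV layout."""
    path = Path(path)
    meas = dataset.measures.rename(columns={"sample_id": "Sample", "seed_id": "Seed"})
    meas = meas[["Sample", "Seed"] + SIZE_COLUMNS]
    coef = dataset.coeffs.reset_index().rename(columns={"seed_id": "Seed"})
    coef.insert(0, "Sample", coef["Seed"].str.rsplit("-", n=1).str[0])
    coef = coef[["Sample", "Seed"] + COEFF_COLUMNS]
    if path.suffix.lower() == ".xlsx":
        with pd.ExcelWriter(path) as writer:
            meas.to_excel(writer, sheet_name="Discrete measures", index=False)
            coef.to_excel(writer, sheet_name="Fourier coefficients", index=False)
    else:
        meas.to_csv(path, index=False, float_format="%.12g")
        if coeff_path is None:
            coeff_path = path.with_name(path.stem + "_coefficients" + path.suffix)
        coef.to_csv(coeff_path, index=False, float_format="%.12g")
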