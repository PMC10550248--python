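"""Domain types, file readers/writers and run configuration.

The package's canonical containers are deliberately plain: specimen and
vegetation-index tables are :class:`pandas.DataFrame` objects with fixed
column schemas, and a cranial landmark configuration is a small dataclass
wrapping a ``(k, 3)`` coordinate array together with a bilateral pairing
map.  All readers validate their input and report offending rows by
position instead of silently dropping them.

File formats
------------
* Specimen CSV — columns ``specimen_id, property, sex, molar_index,
  weight_kg, pes_length_cm`` (comma separated, ``.`` decimal, UTF-8).
* TPS landmark records (``LM3=k`` blocks followed by ``k`` coordinate
  lines and an ``ID=`` line) or a long CSV with columns
  ``specimen, landmark, x, y, z``.
* Pairing sidecar CSV — ``landmark_index, role, partner_index`` with role
  one of ``left``/``right``/``midline``.
* Vegetation-index long CSV — ``cell_id, lat, lon, date, evi, site`` with
  ISO-8601 dates.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

# Enumerations (the two properties sit north/south of the dingo barrier
# fence and are labelled by dingo density, not geography).
PROPERTIES = ("dingoes_common", "dingoes_rare")
SEXES = ("female", "male")
SITES = ("north", "south")

# Molar-index aging curve: log_e(age in days) = a + b * M.
AGE_INTERCEPT = 2.2278
AGE_SLOPE = 0.359
DAYS_PER_YEAR = 365.25

SPECIMEN_COLUMNS = [
    "specimen_id",
    "property",
    "sex",
    "molar_index",
    "weight_kg",
    "pes_length_cm",
]

EVI_COLUMNS = ["cell_id", "lat", "lon", "date", "evi", "site"]


class SchemaError(ValueError):
    """A file is missing required columns or is otherwise malformed."""


class FormatError(ValueError):
    """A landmark file violates its format contract."""


class PairingError(ValueError):
    """A bilateral pairing map does not cover the landmarks exactly once."""


class ConfigError(ValueError):
    """A run configuration or generator specification is invalid."""


@dataclass
class RowError:
    """Diagnostic for a rejected input row."""

    row: int
    column: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row}, column {self.column!r}: {self.message}"


@dataclass
class ReadResult:
    """Validated records plus located diagnostics for rejected rows."""

    records: pd.DataFrame
    errors: list[RowError] = field(default_factory=list)


@dataclass(frozen=True)
class PairingMap:
    """Bilateral landmark pairing: mirror pairs plus midline indices.

    Every landmark index 0..k-1 must appear exactly once, either in one
    ``(left, right)`` pair or in the midline list.
    """

    pairs: tuple[tuple[int, int], ...]
    midline: tuple[int, ...]

    @property
    def n_landmarks(self) -> int:
        return 2 * len(self.pairs) + len(self.midline)

    def validate(self, k: int) -> None:
        seen: list[int] = []
        for left, right in self.pairs:
            seen.extend((left, right))
        seen.extend(self.midline)
        if sorted(seen) != list(range(k)):
            missing = sorted(set(range(k)) - set(seen))
            dupes = sorted({i for i in seen if seen.count(i) > 1})
            parts = []
            if missing:
                parts.append(f"unassigned landmark indices {missing}")
            if dupes:
                parts.append(f"duplicated landmark indices {dupes}")
            raise PairingError(
                "pairing map must cover every landmark exactly once: "
                + "; ".join(parts or ["wrong landmark count"])
            )


@dataclass
class LandmarkConfiguration:
    """One specimen's raw 3D landmarks (unit-agnostic coordinates)."""

    specimen_id: str
    coordinates: np.ndarray  # (k, 3)
    labels: list[str] = field(default_factory=list)
    pairing: PairingMap | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise FormatError(
                f"{self.specimen_id}: coordinates must be (k, 3), "
                f"got {self.coordinates.shape}"
            )
        k = self.coordinates.shape[0]
        if k < 4:
            raise FormatError(f"{self.specimen_id}: need at least 4 landmarks, got {k}")
        if not np.all(np.isfinite(self.coordinates)):
            raise FormatError(f"{self.specimen_id}: non-finite coordinates")
        if not self.labels:
            self.labels = [f"lm{i}" for i in range(k)]
        if len(self.labels) != k:
            raise FormatError(f"{self.specimen_id}: {len(self.labels)} labels for {k} landmarks")
        if self.pairing is not None:
            self.pairing.validate(k)

    @property
    def k(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class RunConfig:
    """Seeds, iteration counts and paths controlling a full pipeline run."""

    seeds: dict[str, int] = field(
        default_factory=lambda: {
            "specimens": 10,
            "landmarks": 20,
            "evi": 30,
            "permlm": 40,
            "randomization": 50,
        }
    )
    n_perm_shape: int = 1000
    n_iter_randomization: int = 10000
    window_length: int = 6
    alpha: float = 0.05
    age_scale: float = 1.0  # post-hoc multiplier on the aging formula output
    out_dir: str = "results"
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "demography": True,
            "growth": True,
            "morphometrics": True,
            "vegetation": True,
        }
    )

    def __post_init__(self) -> None:
        if self.n_perm_shape < 1 or self.n_iter_randomization < 1:
            raise ConfigError("iteration counts must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        for key in ("seeds", "stages"):
            if key in raw:
                merged = dict(getattr(base, key))
                merged.update(raw[key])
                raw[key] = merged
        return cls(**{**dataclasses.asdict(base), **raw})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# specimen tables
# ---------------------------------------------------------------------------

def _check_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def validate_specimens(df: pd.DataFrame) -> ReadResult:
    """Row-validate a specimen table against the domain invariants.

    Rows failing an invariant (unknown property/sex, negative molar index,
    non-positive weight or pes length, inconsistent derived age) are
    excluded and reported with their 0-based row position.
    """
    errors: list[RowError] = []
    keep = np.ones(len(df), dtype=bool)
    df = df.reset_index(drop=True)

    def reject(i: int, column: str, message: str) -> None:
        errors.append(RowError(row=i, column=column, message=message))
        keep[i] = False

    for i, row in df.iterrows():
        if row["property"] not in PROPERTIES:
            reject(i, "property", f"unknown property {row['property']!r}")
        if row["sex"] not in SEXES:
            reject(i, "sex", f"unknown sex {row['sex']!r}")
        for col in ("molar_index", "weight_kg", "pes_length_cm"):
            val = row[col]
            if pd.isna(val):
                continue  # optional measurements may be absent
            if not math.isfinite(val):
                reject(i, col, f"non-finite value {val!r}")
            elif col == "molar_index" and val < 0:
                reject(i, col, f"molar index must be >= 0, got {val}")
            elif col != "molar_index" and val <= 0:
                reject(i, col, f"must be strictly positive, got {val}")
        if "age_days" in df.columns and not pd.isna(row.get("age_days")):
            expected = math.exp(AGE_INTERCEPT + AGE_SLOPE * row["molar_index"])
            if not math.isclose(row["age_days"], expected, rel_tol=1e-6):
                reject(i, "age_days", f"age {row['age_days']} inconsistent with molar index")
    return ReadResult(records=df.loc[keep].reset_index(drop=True), errors=errors)


def read_specimens(path: str | Path, sep: str = ",") -> ReadResult:
    """Read and validate a specimen CSV.

    Numeric columns that fail to parse are reported per cell; the
    offending rows are excluded from the returned table.
    """
    df = pd.read_csv(path, sep=sep, dtype={"specimen_id": str})
    _check_columns(df, SPECIMEN_COLUMNS, str(path))
    errors: list[RowError] = []
    keep = np.ones(len(df), dtype=bool)
    for col in ("molar_index", "weight_kg", "pes_length_cm"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append(
                RowError(row=int(i), column=col, message=f"cannot parse {df[col].iloc[i]!r} as a number")
            )
            keep[i] = False
        df[col] = parsed.astype(float)
    result = validate_specimens(df.loc[keep].reset_index(drop=True))
    # re-map row numbers of the second validation pass onto original rows
    surviving = np.flatnonzero(keep)
    for err in result.errors:
        err.row = int(surviving[err.row])
    result.errors = errors + result.errors
    return result


def write_specimens(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    cols = [c for c in SPECIMEN_COLUMNS if c in df.columns]
    df.to_csv(path, sep=sep, index=False, columns=cols, float_format="%.10g")


# ---------------------------------------------------------------------------
# landmarks: TPS and long CSV
# ---------------------------------------------------------------------------

def read_tps(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Parse a 3D TPS file into ``(specimen_id, (k, 3) array)`` records."""
    records: list[tuple[str, np.ndarray]] = []
    coords: list[list[float]] = []
    expect = 0
    name = ""
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3=") or upper.startswith("LM="):
                if coords:
                    raise FormatError(f"{path}:{lineno}: new LM3 block before ID= line")
                expect = int(line.split("=", 1)[1])
                coords = []
                name = ""
            elif upper.startswith("ID="):
                name = line.split("=", 1)[1].strip()
                if len(coords) != expect:
                    raise FormatError(
                        f"{path}:{lineno}: record {name!r} has {len(coords)} "
                        f"coordinate lines, expected {expect}"
                    )
                records.append((name, np.asarray(coords, dtype=float)))
                coords = []
                expect = 0
            elif "=" in line and not line[0].isdigit() and not line[0] in "-+.":
                continue  # IMAGE=, SCALE=, ... ignored
            else:
                parts = line.split()
                if len(parts) != 3:
                    raise FormatError(f"{path}:{lineno}: expected 3 coordinates, got {len(parts)}")
                coords.append([float(p) for p in parts])
    if coords:
        raise FormatError(f"{path}: trailing coordinate block without ID= line")
    return records


def write_tps(configs: Iterable[LandmarkConfiguration] | Iterable[tuple[str, np.ndarray]],
              path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for item in configs:
            if isinstance(item, LandmarkConfiguration):
                name, xyz = item.specimen_id, item.coordinates
            else:
                name, xyz = item
            fh.write(f"LM3={xyz.shape[0]}\n")
            for row in xyz:
                fh.write("{:.12g} {:.12g} {:.12g}\n".format(*row))
            fh.write(f"ID={name}\n")


def read_pairing(path: str | Path) -> PairingMap:
    df = pd.read_csv(path)
    _check_columns(df, ["landmark_index", "role", "partner_index"], str(path))
    pairs: list[tuple[int, int]] = []
    midline: list[int] = []
    for _, row in df.iterrows():
        role = row["role"]
        idx = int(row["landmark_index"])
        if role == "left":
            pairs.append((idx, int(row["partner_index"])))
        elif role == "midline":
            midline.append(idx)
        elif role != "right":
            raise PairingError(f"unknown role {role!r} for landmark {idx}")
    return PairingMap(pairs=tuple(pairs), midline=tuple(midline))


def write_pairing(pairing: PairingMap, path: str | Path) -> None:
    rows = []
    for left, right in pairing.pairs:
        rows.append({"landmark_index": left, "role": "left", "partner_index": right})
        rows.append({"landmark_index": right, "role": "right", "partner_index": left})
    for idx in pairing.midline:
        rows.append({"landmark_index": idx, "role": "midline", "partner_index": ""})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks(
    path: str | Path,
    format: str = "tps",
    pairing_path: str | Path | None = None,
) -> list[LandmarkConfiguration]:
    """Read landmark configurations (TPS or long CSV) plus pairing sidecar.

    All specimens in one file must share the same landmark count; the
    pairing map, when given, must cover that count exactly.
    """
    if format == "tps":
        raw = read_tps(path)
    elif format == "delimited":
        df = pd.read_csv(path)
        _check_columns(df, ["specimen", "landmark", "x", "y", "z"], str(path))
        raw = []
        for name, grp in df.groupby("specimen", sort=False):
            grp = grp.sort_values("landmark")
            raw.append((str(name), grp[["x", "y", "z"]].to_numpy(dtype=float)))
    else:
        raise ValueError(f"unknown landmark format {format!r}")

    ks = {xyz.shape[0] for _, xyz in raw}
    if len(ks) > 1:
        raise FormatError(f"{path}: inconsistent landmark counts across specimens: {sorted(ks)}")
    pairing = read_pairing(pairing_path) if pairing_path is not None else None
    return [
        LandmarkConfiguration(specimen_id=name, coordinates=xyz, pairing=pairing)
        for name, xyz in raw
    ]


def write_landmarks_csv(configs: Iterable[LandmarkConfiguration], path: str | Path) -> None:
    rows = []
    for cfg in configs:
        for j, (x, y, z) in enumerate(cfg.coordinates):
            rows.append({"specimen": cfg.specimen_id, "landmark": j, "x": x, "y": y, "z": z})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# vegetation-index tables
# ---------------------------------------------------------------------------

def read_evi(path: str | Path, check_cadence: bool = True) -> pd.DataFrame:
    """Read a long-format vegetation-index CSV, parsing ISO dates."""
    df = pd.read_csv(path, dtype={"cell_id": str})
    _check_columns(df, EVI_COLUMNS, str(path))
    df["date"] = pd.to_datetime(df["date"])
    bad_site = ~df["site"].isin(SITES)
    if bad_site.any():
        raise SchemaError(
            f"{path}: unknown site value(s) {sorted(df.loc[bad_site, 'site'].unique())}"
        )
    if check_cadence:
        validate_cadence(df)
    return df.sort_values(["site", "cell_id", "date"]).reset_index(drop=True)


def validate_cadence(df: pd.DataFrame) -> int:
    """Check every (site, cell) series sits on one regular day cadence."""
    cadences = set()
    for (site, cell), grp in df.groupby(["site", "cell_id"]):
        steps = grp["date"].sort_values().diff().dropna().dt.days.unique()
        if len(steps) > 1:
            raise SchemaError(
                f"irregular cadence for site {site!r} cell {cell!r}: steps {sorted(steps)} days"
            )
        if len(steps):
            cadences.add(int(steps[0]))
    if len(cadences) > 1:
        raise SchemaError(f"mixed cadences across cells: {sorted(cadences)} days")
    return cadences.pop() if cadences else 0


def write_evi(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, columns=EVI_COLUMNS, float_format="%.10g")
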