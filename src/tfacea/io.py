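"""Reading, validation and writing of model inputs and outputs.

Input tables travel as UTF-8 CSV with a header row and dot decimals:

* ``life_table.csv`` — columns ``age, sex, q_all_cause``
* ``morbidity.csv`` — columns ``age, sex, p_cad_first, case_fatality``
* ``population.csv`` — columns ``age, sex, count``

``sex`` is ``F`` or ``M``; ``age`` is an integer year.  Every table must
cover the same complete, contiguous (age, sex) grid.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import ClassVar, Mapping

import numpy as np
import pandas as pd

from .config import InputDataError, RunConfig, SEXES, load_run_config

#: CSV float format preserving doubles exactly in a text round-trip.
FLOAT_FORMAT = "%.17g"


def _fail(msg: str) -> None:
    raise InputDataError(msg)


@dataclass(frozen=True)
class AgeSexTable:
    """A complete (age, sex) grid of one or more numeric columns."""

    frame: pd.DataFrame

    #: subclasses set: column name -> kind ("probability" or "count")
    columns: ClassVar[Mapping[str, str]] = {}
    filename: ClassVar[str] = "table.csv"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self, source: str | None = None) -> None:
        src = source or self.filename
        df = self.frame
        expected = ["age", "sex", *self.columns]
        missing = [c for c in expected if c not in df.columns]
        if missing:
            _fail(f"{src}: missing column(s) {missing}")
        for col, kind in self.columns.items():
            vals = df[col].to_numpy(dtype=float)
            bad = ~np.isfinite(vals)
            if kind == "probability":
                bad |= (vals < 0) | (vals > 1)
            else:  # count
                bad |= vals < 0
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                row = df.iloc[i]
                _fail(
                    f"{src}: row {i} (age={row['age']}, sex={row['sex']}): "
                    f"field {col!r} = {row[col]!r} is not a valid {kind}"
                )
        sexes = set(df["sex"].unique())
        if sexes != set(SEXES):
            _fail(f"{src}: field 'sex' must cover exactly {set(SEXES)}, found {sexes}")
        ages = np.sort(df.loc[df["sex"] == SEXES[0], "age"].to_numpy(dtype=int))
        if len(ages) == 0 or not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
            _fail(f"{src}: ages must form a contiguous integer range, got {ages.tolist()[:20]}")
        for s in SEXES:
            a = np.sort(df.loc[df["sex"] == s, "age"].to_numpy(dtype=int))
            if not np.array_equal(a, ages):
                _fail(f"{src}: age grid for sex {s!r} does not match sex {SEXES[0]!r}")
        if df.duplicated(subset=["age", "sex"]).any():
            _fail(f"{src}: duplicate (age, sex) rows")

    # -- structure ----------------------------------------------------------
    @property
    def ages(self) -> np.ndarray:
        return np.sort(self.frame.loc[self.frame["sex"] == SEXES[0], "age"].unique()).astype(int)

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def as_array(self, column: str) -> np.ndarray:
        """Values as an array of shape (n_ages, 2) ordered by age, sex (F, M)."""
        cache = getattr(self, "_array_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_array_cache", cache)
        if column not in cache:
            pivot = self.frame.pivot(index="age", columns="sex", values=column).sort_index()
            cache[column] = pivot[list(SEXES)].to_numpy(dtype=float)
        return cache[column]

    def same_grid(self, other: "AgeSexTable") -> bool:
        return np.array_equal(self.ages, other.ages)

    # -- IO -----------------------------------------------------------------
    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.frame[["age", "sex", *self.columns]].sort_values(["sex", "age"])
        out.to_csv(path, index=False, float_format=FLOAT_FORMAT)
        return path

    @classmethod
    def read_csv(cls, path: str | Path):
        path = Path(path)
        if not path.exists():
            _fail(f"{path}: file not found")
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except Exception as e:  # malformed CSV
            raise InputDataError(f"{path}: cannot parse CSV ({e})") from e
        table = cls.__new__(cls)
        object.__setattr__(table, "frame", df)
        table.validate(source=str(path))
        return table

    @classmethod
    def from_arrays(cls, ages: np.ndarray, **columns: np.ndarray):
        """Build from per-column arrays of shape (n_ages, 2), sex order (F, M)."""
        rows = []
        for si, s in enumerate(SEXES):
            block = pd.DataFrame({"age": np.asarray(ages, dtype=int), "sex": s})
            for col in cls.columns:
                block[col] = np.asarray(columns[col], dtype=float)[:, si]
            rows.append(block)
        return cls(pd.concat(rows, ignore_index=True))


@dataclass(frozen=True)
class LifeTable(AgeSexTable):
    """Annual all-cause death probability q(age, sex)."""

    columns: ClassVar[Mapping[str, str]] = {"q_all_cause": "probability"}
    filename: ClassVar[str] = "life_table.csv"


@dataclass(frozen=True)
class MorbidityTable(AgeSexTable):
    """Annual first-CAD-event probability and acute-event case fatality."""

    columns: ClassVar[Mapping[str, str]] = {
        "p_cad_first": "probability",
        "case_fatality": "probability",
    }
    filename: ClassVar[str] = "morbidity.csv"


@dataclass(frozen=True)
class PopulationPyramid(AgeSexTable):
    """Person counts by (age, sex)."""

    columns: ClassVar[Mapping[str, str]] = {"count": "count"}
    filename: ClassVar[str] = "population.csv"

    @property
    def total(self) -> float:
        return float(self.frame["count"].sum())


@dataclass(frozen=True)
class InputBundle:
    """The validated trio of input tables sharing one (age, sex) grid."""

    life: LifeTable
    morbidity: MorbidityTable
    population: PopulationPyramid

    def __post_init__(self) -> None:
        if not (self.life.same_grid(self.morbidity) and self.life.same_grid(self.population)):
            _fail("life table, morbidity table and population pyramid must share one age-sex grid")


def read_inputs(data_dir: str | Path, run_config_path: str | Path | None = None,
                ) -> tuple[LifeTable, MorbidityTable, PopulationPyramid, RunConfig | None]:
    """Read and validate the three input tables (and optionally a run config).

    ``data_dir`` must contain ``life_table.csv``, ``morbidity.csv`` and
    ``population.csv``.  Raises :class:`InputDataError` naming the offending
    file, row and field on any validation failure.
    """
    data_dir = Path(data_dir)
    life = LifeTable.read_csv(data_dir / LifeTable.filename)
    morbidity = MorbidityTable.read_csv(data_dir / MorbidityTable.filename)
    population = PopulationPyramid.read_csv(data_dir / PopulationPyramid.filename)
    InputBundle(life, morbidity, population)  # cross-table grid check
    cfg = load_run_config(run_config_path) if run_config_path is not None else None
    return life, morbidity, population, cfg


def write_results(out_dir: str | Path,
                  results_by_option: pd.DataFrame,
                  incremental: pd.DataFrame,
                  psa_draws: pd.DataFrame | None = None,
                  ce_plane: pd.DataFrame | None = None,
                  summary: dict | None = None) -> dict[str, Path]:
    """Write analysis outputs as CSV/JSON with full float precision.

    Empty frames yield header-only files, so downstream tooling always finds
    the same set of columns.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise InputDataError(f"cannot create output directory {out_dir}: {e}") from e

    written: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
        written[name] = path

    _write("results_by_option.csv", results_by_option)
    _write("incremental.csv", incremental)
    if psa_draws is not None:
        _write("psa_draws.csv", psa_draws)
    if ce_plane is not None:
        _write("ce_plane.csv", ce_plane)
    if summary is not None:
        path = out_dir / "summary.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        written["summary.json"] = path
    return written
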