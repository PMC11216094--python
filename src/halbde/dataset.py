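"""BDE tables: loading, validation, min-max scaling, and train/test splitting.

The packaged fixtures hold the computed homolytic and heterolytic bond
dissociation energies (kcal/mol) for the 5 skeletons x 3 halogen centers x
20 transfer groups of the study, one row per table cell.  Missing cells are
kept as records with ``missing=True``; the two printed missing-value
sentinels ("dash" and "slash") are preserved for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import BDEParseError, DegenerateScaleError, IntegrityError

FIXTURE_COLUMNS = ["skeleton_id", "halogen", "group_id", "group_label",
                   "bde_kcal_mol", "sentinel"]
SENTINELS = {"dash", "slash"}

Key = tuple[int, str, str]


@dataclass(frozen=True)
class BDERecord:
    """A single BDE table cell."""

    skeleton_id: int
    halogen: str
    group_id: str
    group_label: str
    bde_type: str          # "homolytic" | "heterolytic"
    value: float | None
    missing: bool = False
    sentinel: str | None = None

    @property
    def key(self) -> Key:
        return (self.skeleton_id, self.halogen, self.group_id)


def load_bde_table(path: str | Path, bde_type: str) -> list[BDERecord]:
    """Load a fixture-schema CSV into one :class:`BDERecord` per cell.

    Cells flagged with a missing-value sentinel become ``missing`` records;
    all other cells must be numeric.

    Raises
    ------
    BDEParseError
        A cell is neither numeric nor a recognised sentinel (the message
        names the offending (skeleton, halogen, group) address).
    IntegrityError
        Duplicate (skeleton, halogen, group) keys.
    """
    if bde_type not in ("homolytic", "heterolytic"):
        raise ValueError(f"bde_type must be homolytic|heterolytic, got {bde_type!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != FIXTURE_COLUMNS:
        raise IntegrityError(
            f"unexpected fixture columns {list(df.columns)}; want {FIXTURE_COLUMNS}")
    records: list[BDERecord] = []
    seen: set[Key] = set()
    for row in df.itertuples(index=False):
        key = (int(row.skeleton_id), row.halogen, row.group_id)
        if key in seen:
            raise IntegrityError(f"duplicate record key {key}")
        seen.add(key)
        sentinel = row.sentinel or None
        raw = row.bde_kcal_mol.strip()
        if sentinel is not None:
            if sentinel not in SENTINELS:
                raise BDEParseError(f"unknown sentinel {sentinel!r} at {key}")
            if raw:
                raise BDEParseError(f"cell {key} has both a value and a sentinel")
            value, missing = None, True
        else:
            try:
                value = float(raw)
            except ValueError:
                raise BDEParseError(
                    f"non-numeric, non-sentinel cell {raw!r} at skeleton "
                    f"{key[0]}, halogen {key[1]}, group {key[2]}") from None
            missing = False
        records.append(BDERecord(key[0], row.halogen, row.group_id,
                                 row.group_label, bde_type, value,
                                 missing, sentinel))
    return records


def _fixture_path(name: str):
    return resources.files("halbde.data") / name


def load_homolytic() -> list[BDERecord]:
    """The packaged homolytic BDE table (300 cells, all numeric)."""
    return load_bde_table(_fixture_path("homolytic.csv"), "homolytic")


def load_heterolytic() -> list[BDERecord]:
    """The packaged heterolytic BDE table (300 cells, 209 numeric)."""
    return load_bde_table(_fixture_path("heterolytic.csv"), "heterolytic")


def load_external_table() -> pd.DataFrame:
    """External-test reagents: DFT reference values and the published
    linear-equation (LE) and machine-learning (ML) predictions."""
    return pd.read_csv(_fixture_path("external_test.csv"))


def load_le_equations() -> pd.DataFrame:
    """Published cross-halogen linear-dependence equations (slope, intercept)."""
    return pd.read_csv(_fixture_path("le_equations.csv"))


def non_missing(records: Iterable[BDERecord]) -> list[BDERecord]:
    return [r for r in records if not r.missing]


def records_to_frame(records: Iterable[BDERecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "skeleton_id": r.skeleton_id, "halogen": r.halogen,
        "group_id": r.group_id, "group_label": r.group_label,
        "bde_type": r.bde_type, "bde_kcal_mol": r.value, "missing": r.missing,
    } for r in records])


# ---------------------------------------------------------------------------
# min-max scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalerParams:
    """Affine min-max normalisation to [0, 1] (kcal/mol bounds)."""

    min_value: float
    max_value: float

    def __post_init__(self):
        if not self.max_value > self.min_value:
            raise DegenerateScaleError(
                f"degenerate scale: max ({self.max_value}) must exceed "
                f"min ({self.min_value})")

    def transform(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return (v - self.min_value) / (self.max_value - self.min_value)

    def inverse_transform(self, scaled) -> np.ndarray:
        s = np.asarray(scaled, dtype=float)
        return s * (self.max_value - self.min_value) + self.min_value


def minmax_scale(values: Sequence[float]) -> tuple[np.ndarray, ScalerParams]:
    """Scale to [0, 1]; the minimum maps to 0 and the maximum to 1.

    Raises :class:`DegenerateScaleError` for constant input rather than
    dividing by zero.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DegenerateScaleError("need at least two values to fit a scaler")
    params = ScalerParams(float(v.min()), float(v.max()))
    return params.transform(v), params


# ---------------------------------------------------------------------------
# train/test splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/test partition of record keys (one reagent = one record)."""

    train: tuple[Key, ...]
    test: tuple[Key, ...]
    seed: int
    test_fraction: float = 0.1

    def __post_init__(self):
        overlap = set(self.train) & set(self.test)
        if overlap:
            raise IntegrityError(f"train/test overlap: {sorted(overlap)[:3]}...")


def split_dataset(records: Sequence[BDERecord], test_fraction: float = 0.1,
                  seed: int = 0) -> DatasetSplit:
    """Random 9:1-style partition of non-missing records, reproducible by seed.

    ``|test| = round(test_fraction * N)`` with half-up rounding; no
    stratification is applied.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    recs = list(records)
    if not recs:
        raise ValueError("no records to split")
    if any(r.missing for r in recs):
        raise ValueError("records must be non-missing; filter first")
    keys = [r.key for r in recs]
    n_test = int(np.floor(test_fraction * len(keys) + 0.5))
    n_test = max(1, min(n_test, len(keys) - 1))
    order = np.random.default_rng(seed).permutation(len(keys))
    test = tuple(keys[i] for i in sorted(order[:n_test]))
    train = tuple(keys[i] for i in sorted(order[n_test:]))
    return DatasetSplit(train=train, test=test, seed=seed,
                        test_fraction=test_fraction)
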