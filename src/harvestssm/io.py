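"""File formats: the harvest registry CSV dialect and result exports.

Registry dialect (long format): columns ``year``, ``sex`` in {F, M, U},
``age_class`` in {1.5, 2.5, ..., 9.5, 10.5+, unknown}, ``count``. Totals
``O_y`` are the per-year sums including the unknown rows; the aged/sexed
array ``C`` collects the known rows only.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .observation import HarvestData
from .population import SEX_LABELS, age_class_labels

__all__ = [
    "RegistryFormatError",
    "file_digest",
    "read_permits",
    "read_registry",
    "write_registry",
]

_REQUIRED_COLUMNS = ("year", "sex", "age_class", "count")


class RegistryFormatError(ValueError):
    """Raised when a registry CSV violates the dialect or the data invariants."""


def write_registry(data: HarvestData, path: str | Path) -> None:
    """Write a harvest registry in the long CSV dialect (text only)."""
    labels = data.age_labels
    rows = []
    for y_idx, year in enumerate(data.years):
        for s in range(2):
            for a in range(data.n_age_classes):
                count = int(data.C[a, s, y_idx])
                if count:
                    rows.append((int(year), SEX_LABELS[s], labels[a], count))
        unknown = int(data.O[y_idx] - data.n_aged[y_idx])
        if unknown:
            rows.append((int(year), "U", "unknown", unknown))
    frame = pd.DataFrame(rows, columns=_REQUIRED_COLUMNS)
    frame.to_csv(path, index=False)


def read_registry(path: str | Path, n_age_classes: int = 10,
                  totals_path: str | Path | None = None) -> HarvestData:
    """Parse a registry CSV; errors name the offending line.

    If ``totals_path`` (a two-column ``year,O`` CSV) is given, the derived
    totals are cross-checked against it and must match exactly.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise RegistryFormatError(f"{path}: missing column(s) {', '.join(missing)}")

    labels = age_class_labels(n_age_classes)
    label_index = {lab: i for i, lab in enumerate(labels)}
    year_list: list[int] = []
    parsed = []
    columns = zip(frame["year"], frame["sex"], frame["age_class"], frame["count"])
    for pos, (raw_year, raw_sex, raw_age, raw_count) in enumerate(columns, start=2):
        try:
            year = int(raw_year)
            count = int(raw_count)
        except ValueError:
            raise RegistryFormatError(
                f"{path}, line {pos}: year and count must be integers"
            ) from None
        if count < 0:
            raise RegistryFormatError(f"{path}, line {pos}: negative count")
        sex = raw_sex.strip()
        age = raw_age.strip()
        if sex not in ("F", "M", "U"):
            raise RegistryFormatError(f"{path}, line {pos}: sex must be F, M or U")
        known = sex in ("F", "M") and age != "unknown"
        if known and age not in label_index:
            raise RegistryFormatError(
                f"{path}, line {pos}: unknown age class {age!r}"
            )
        if year not in year_list:
            year_list.append(year)
        parsed.append((year, sex, age, count, known))
    if not parsed:
        raise RegistryFormatError(f"{path}: registry is empty")

    years = np.array(sorted(year_list))
    y_index = {int(y): i for i, y in enumerate(years)}
    O = np.zeros(len(years), dtype=int)
    C = np.zeros((n_age_classes, 2, len(years)), dtype=int)
    for year, sex, age, count, known in parsed:
        yi = y_index[year]
        O[yi] += count
        if known:
            C[label_index[age], SEX_LABELS.index(sex), yi] += count
    data = HarvestData(years=years, O=O, C=C)

    if totals_path is not None:
        totals = pd.read_csv(totals_path)
        if not {"year", "O"} <= set(totals.columns):
            raise RegistryFormatError(f"{totals_path}: totals file needs year,O columns")
        declared = {int(r.year): int(r.O) for r in totals.itertuples(index=False)}
        for year, o in zip(data.years, data.O):
            if int(year) in declared and declared[int(year)] != int(o):
                raise RegistryFormatError(
                    f"totals mismatch in year {int(year)}: registry sums to {int(o)}, "
                    f"totals file declares {declared[int(year)]}"
                )
    return data


def read_permits(path: str | Path, years: np.ndarray) -> np.ndarray:
    """Read a ``year,permits`` CSV aligned to the given years."""
    frame = pd.read_csv(path)
    if not {"year", "permits"} <= set(frame.columns):
        raise RegistryFormatError(f"{path}: permits file needs year,permits columns")
    lookup = {int(r.year): int(r.permits) for r in frame.itertuples(index=False)}
    try:
        return np.array([lookup[int(y)] for y in years])
    except KeyError as exc:
        raise RegistryFormatError(f"{path}: no permit count for year {exc}") from None


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
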