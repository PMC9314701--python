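"""Effect-concentration records for nano- and microplastic (NMP) toxicity data.

One :class:`EffectRecord` is a single laboratory toxicity observation: a
species exposed to spherical (or fibrous/irregular) plastic particles of a
given polymer and size, in a freshwater, marine or brackish medium, yielding
an effect concentration (LC50, EC50, NOEC, LOEC, ...) that is standardised to
a chronic lowest-observed-effect concentration (chronic LOEC, ug/L) by
dividing by an extrapolation factor between 1 and 30.

Records round-trip through a documented CSV dialect (UTF-8, decimal point,
one row per record) via :func:`read_records_csv` / :func:`write_records_csv`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

EFFECT_TYPES = ("LC50", "EC50", "NOEC", "LOEC", "chronic_LOEC", "other")
SHAPES = ("sphere", "fiber", "irregular")
MEDIA = ("freshwater", "marine", "brackish")

#: CSV column order; every column maps 1:1 to an EffectRecord field.
CSV_COLUMNS = (
    "species_name",
    "phylum",
    "reported_value",
    "effect_type",
    "exposure_duration_days",
    "chronic_loec",
    "size_min_um",
    "size_max_um",
    "size_um",
    "shape",
    "polymer",
    "medium",
    "salinity_permil",
    "reference_id",
    "conversion_factor",
)


class RecordValidationError(ValueError):
    """A record violates a field constraint or invariant."""


class ExtrapolationLookupError(KeyError):
    """No extrapolation factor resolves for a record's effect type/duration."""


def midpoint_size(size_min_um: float, size_max_um: float) -> float:
    """Arithmetic mean of a reported particle-size range (um).

    Used when a study reports only a size range for a single effect
    concentration; the point value entering the model is ``(min + max) / 2``.

    Raises
    ------
    RecordValidationError
        If either bound is nonpositive or the bounds are inverted.
    """
    if not (size_min_um > 0 and size_max_um > 0):
        raise RecordValidationError(
            f"size bounds must be positive, got ({size_min_um}, {size_max_um})"
        )
    if size_min_um > size_max_um:
        raise RecordValidationError(
            f"size_min_um {size_min_um} exceeds size_max_um {size_max_um}"
        )
    return (size_min_um + size_max_um) / 2.0


@dataclass(frozen=True)
class EffectRecord:
    """One NMP toxicity observation with its covariates and provenance.

    ``size_um`` may be given directly (point value) or is filled in as the
    midpoint of ``size_min_um``/``size_max_um`` on construction.
    ``chronic_loec`` is populated by the extrapolation-factor conversion
    (:meth:`ExtrapolationTable`-based), with the applied factor kept in
    ``conversion_factor`` for audit.
    """

    species_name: str
    reference_id: str
    polymer: str
    medium: str
    shape: str = "sphere"
    effect_type: str = "chronic_LOEC"
    reported_value: float | None = None
    exposure_duration_days: float | None = None
    chronic_loec: float | None = None
    size_min_um: float | None = None
    size_max_um: float | None = None
    size_um: float | None = None
    phylum: str | None = None
    salinity_permil: float | None = None
    conversion_factor: float | None = None

    def __post_init__(self) -> None:
        if self.effect_type not in EFFECT_TYPES:
            raise RecordValidationError(
                f"{self.species_name}: effect_type {self.effect_type!r} not in {EFFECT_TYPES}"
            )
        if self.shape not in SHAPES:
            raise RecordValidationError(
                f"{self.species_name}: shape {self.shape!r} not in {SHAPES}"
            )
        if self.medium not in MEDIA:
            raise RecordValidationError(
                f"{self.species_name}: medium {self.medium!r} not in {MEDIA}"
            )
        for name in ("reported_value", "chronic_loec", "exposure_duration_days"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise RecordValidationError(
                    f"{self.species_name}: {name} must be > 0, got {v}"
                )
        if self.size_um is None and self.size_min_um is not None and self.size_max_um is not None:
            object.__setattr__(
                self, "size_um", midpoint_size(self.size_min_um, self.size_max_um)
            )
        if self.size_um is not None and not self.size_um > 0:
            raise RecordValidationError(
                f"{self.species_name}: size_um must be > 0, got {self.size_um}"
            )
        if self.size_min_um is not None and self.size_max_um is not None:
            if not self.size_min_um <= self.size_max_um:
                raise RecordValidationError(
                    f"{self.species_name}: size range inverted "
                    f"({self.size_min_um}, {self.size_max_um})"
                )
            if self.size_um is not None and not (
                self.size_min_um <= self.size_um <= self.size_max_um
            ):
                raise RecordValidationError(
                    f"{self.species_name}: size_um {self.size_um} outside range "
                    f"({self.size_min_um}, {self.size_max_um})"
                )

    def replace(self, **changes) -> "EffectRecord":
        return replace(self, **changes)


@dataclass(frozen=True)
class ExtrapolationRule:
    """One row of the extrapolation table: (effect type, duration window) -> factor."""

    effect_type: str
    factor: float
    min_days: float | None = None  # inclusive; None = unbounded below
    max_days: float | None = None  # inclusive; None = unbounded above

    def __post_init__(self) -> None:
        if not 1.0 <= self.factor <= 30.0:
            raise RecordValidationError(
                f"extrapolation factor must lie in [1, 30], got {self.factor}"
            )
        if self.effect_type not in EFFECT_TYPES:
            raise RecordValidationError(
                f"unknown effect_type {self.effect_type!r} in extrapolation rule"
            )

    def matches(self, effect_type: str, duration_days: float | None) -> bool:
        if effect_type != self.effect_type:
            return False
        if duration_days is None:
            return self.min_days is None and self.max_days is None
        if self.min_days is not None and duration_days < self.min_days:
            return False
        if self.max_days is not None and duration_days > self.max_days:
            return False
        return True


class ExtrapolationTable:
    """User-editable mapping from (effect type, exposure duration) to a divisor.

    Chronic LOECs pass through with factor 1. All factors are constrained to
    [1, 30]. The shipped :meth:`default` table is an illustrative placeholder:
    compiled datasets normally arrive with their own conversion table (or with
    pre-converted chronic LOECs), which users load via :meth:`from_json`.
    """

    def __init__(self, rules: Sequence[ExtrapolationRule]):
        self.rules = list(rules)

    def lookup(self, effect_type: str, duration_days: float | None) -> float:
        if effect_type == "chronic_LOEC":
            return 1.0
        for rule in self.rules:
            if rule.matches(effect_type, duration_days):
                return rule.factor
        raise ExtrapolationLookupError(
            f"no extrapolation factor for effect_type={effect_type!r}, "
            f"duration={duration_days!r} days"
        )

    @classmethod
    def default(cls) -> "ExtrapolationTable":
        # Illustrative: acute-to-chronic divisors grow as the test shortens.
        return cls(
            [
                ExtrapolationRule("LOEC", 1.0, min_days=21.0),
                ExtrapolationRule("LOEC", 3.0, max_days=21.0),
                ExtrapolationRule("NOEC", 1.0),
                ExtrapolationRule("LC50", 10.0, min_days=21.0),
                ExtrapolationRule("LC50", 30.0, max_days=21.0),
                ExtrapolationRule("EC50", 10.0, min_days=21.0),
                ExtrapolationRule("EC50", 30.0, max_days=21.0),
            ]
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ExtrapolationTable":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls([ExtrapolationRule(**row) for row in raw["rules"]])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rules": [
                {
                    "effect_type": r.effect_type,
                    "factor": r.factor,
                    "min_days": r.min_days,
                    "max_days": r.max_days,
                }
                for r in self.rules
            ]
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def records_to_frame(records: Iterable[EffectRecord]) -> pd.DataFrame:
    rows = [{c: getattr(r, _COL_TO_FIELD[c]) for c in CSV_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[EffectRecord]:
    records = []
    for idx, row in df.iterrows():
        kwargs = {}
        for col in CSV_COLUMNS:
            if col not in df.columns:
                continue
            v = row[col]
            if isinstance(v, float) and math.isnan(v):
                v = None
            if pd.isna(v):
                v = None
            if v is None and col in ("effect_type", "shape"):
                continue  # fall back to the field defaults
            kwargs[_COL_TO_FIELD[col]] = v
        try:
            records.append(EffectRecord(**kwargs))
        except RecordValidationError as err:
            raise RecordValidationError(f"row {idx}: {err}") from err
    return records


def read_records_csv(path: str | Path) -> list[EffectRecord]:
    """Read effect records from CSV (columns per :data:`CSV_COLUMNS`)."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = {"species_name", "reference_id", "polymer", "medium"} - set(df.columns)
    if missing:
        raise RecordValidationError(f"{path}: missing required columns {sorted(missing)}")
    return frame_to_records(df)


def write_records_csv(records: Iterable[EffectRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False, encoding="utf-8")


_COL_TO_FIELD = {c: c for c in CSV_COLUMNS}
_COL_TO_FIELD["exposure_duration_days"] = "exposure_duration_days"
assert all(f in {fl.name for fl in fields(EffectRecord)} for f in _COL_TO_FIELD.values())
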