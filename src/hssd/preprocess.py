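"""Preprocessing of effect records into a model-ready dataset.

The chain standardises compiled NMP effect concentrations for SSD fitting:

1. convert reported effect concentrations to chronic LOECs by dividing by an
   extrapolation factor (1-30, by effect type and exposure duration);
2. keep spherical particles only, and re-categorise brackish tests as marine
   unless a per-species override maps them to freshwater (e.g. a low-salinity
   amphipod test belongs with the freshwater records);
3. aggregate replicate effect concentrations observed under identical test
   conditions (species, size, polymer category, medium, reference) to their
   geometric mean;
4. encode predictors: y = log10 chronic LOEC, x_size = log10 particle
   diameter (um), medium dummy (freshwater 0, marine 1), polymer dummy
   (non-PS 0, PS 1), and an integer reference index for the random effect.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import (
    EffectRecord,
    ExtrapolationTable,
    RecordValidationError,
    records_to_frame,
)

logger = logging.getLogger(__name__)

#: Polymer labels coded as PS (polystyrene incl. polystyrene-polyethyleneimine
#: mixtures); matching is case-insensitive on the normalised label.
DEFAULT_PS_LABELS = frozenset(
    {
        "ps",
        "polystyrene",
        "ps-pei",
        "ps+pei",
        "polystyrene-polyethyleneimine",
        "polystyrene+polyethyleneimine",
        "polystyrene + polyethyleneimine",
        "polystyrene/polyethyleneimine",
    }
)

#: Species whose brackish-medium tests are re-categorised as freshwater
#: (low-salinity test conditions); all other brackish tests become marine.
DEFAULT_FRESHWATER_OVERRIDES = frozenset({"hyalella azteca"})


def _norm(label: str) -> str:
    return " ".join(str(label).lower().split())


def convert_to_chronic_loec(
    record: EffectRecord, table: ExtrapolationTable
) -> EffectRecord:
    """Standardise one record's effect concentration to a chronic LOEC.

    ``chronic_loec = reported_value / factor`` where the factor comes from the
    extrapolation table; records already carrying a chronic LOEC pass through
    with factor 1. The applied factor is stored on the record for audit.
    """
    if record.effect_type == "chronic_LOEC":
        value = record.chronic_loec if record.chronic_loec is not None else record.reported_value
        if value is None:
            raise RecordValidationError(
                f"{record.species_name}: chronic_LOEC record carries no value"
            )
        return record.replace(chronic_loec=value, conversion_factor=1.0)
    if record.reported_value is None:
        raise RecordValidationError(
            f"{record.species_name}: no reported_value to convert"
        )
    factor = table.lookup(record.effect_type, record.exposure_duration_days)
    return record.replace(
        chronic_loec=record.reported_value / factor, conversion_factor=factor
    )


def filter_and_recategorize(
    records: Sequence[EffectRecord],
    freshwater_overrides: Iterable[str] = DEFAULT_FRESHWATER_OVERRIDES,
) -> list[EffectRecord]:
    """Keep spherical-particle records and resolve brackish media.

    Non-spherical records (fibers, irregular fragments) are dropped to
    minimise shape effects. Brackish records are reassigned to marine, except
    species named in ``freshwater_overrides`` (case-insensitive), which become
    freshwater. The output contains no brackish records; concentrations and
    sizes are never altered.
    """
    overrides = {_norm(s) for s in freshwater_overrides}
    out: list[EffectRecord] = []
    n_dropped = n_marine = n_fresh = 0
    for rec in records:
        if rec.shape != "sphere":
            n_dropped += 1
            continue
        if rec.medium == "brackish":
            if _norm(rec.species_name) in overrides:
                rec = rec.replace(medium="freshwater")
                n_fresh += 1
            else:
                rec = rec.replace(medium="marine")
                n_marine += 1
        out.append(rec)
    logger.info(
        "filter_and_recategorize: dropped %d non-spherical; brackish->marine %d, "
        "brackish->freshwater %d; %d records retained",
        n_dropped, n_marine, n_fresh, len(out),
    )
    if not out:
        warnings.warn("all records filtered out; empty dataset", stacklevel=2)
    return out


def aggregate_geometric_mean(
    records: Sequence[EffectRecord],
    ps_labels: Iterable[str] = DEFAULT_PS_LABELS,
) -> list[EffectRecord]:
    """Collapse replicate observations to geometric means.

    Records sharing (species, particle size, polymer category, medium,
    reference) are one test condition; a group of k > 1 chronic LOECs is
    replaced by a single record holding their geometric mean. The grouping key
    includes the reference so every aggregated record still belongs to exactly
    one study for the random effect; same-condition records from *different*
    references are reported at INFO level and kept separate.
    """
    ps = {_norm(x) for x in ps_labels}
    groups: dict[tuple, list[EffectRecord]] = {}
    for rec in records:
        if rec.chronic_loec is None:
            raise RecordValidationError(
                f"{rec.species_name}: chronic_loec missing; run conversion first"
            )
        polymer_cat = "PS" if _norm(rec.polymer) in ps else "other"
        key = (_norm(rec.species_name), rec.size_um, polymer_cat, rec.medium,
               rec.reference_id)
        groups.setdefault(key, []).append(rec)

    condition_refs: dict[tuple, set[str]] = {}
    for key in groups:
        condition_refs.setdefault(key[:4], set()).add(key[4])
    for cond, refs in condition_refs.items():
        if len(refs) > 1:
            logger.info(
                "aggregate: condition %s appears in %d references %s; "
                "kept separate per reference", cond, len(refs), sorted(refs),
            )

    out: list[EffectRecord] = []
    for key, members in groups.items():
        if len(members) == 1:
            out.append(members[0])
        else:
            gm = math.exp(
                sum(math.log(m.chronic_loec) for m in members) / len(members)
            )
            logger.info(
                "aggregate: %d records for %s -> geometric mean %.6g ug/L",
                len(members), key[:4], gm,
            )
            out.append(members[0].replace(chronic_loec=gm))
    return out


@dataclass(frozen=True)
class PreparedDataset:
    """Response and encoded predictors for hierarchical SSD fitting.

    ``ref_index`` holds 0-based consecutive integers assigned by first
    appearance of each ``reference_id`` (so values cover 0..n_refs-1 with no
    gaps); ``ref_ids[j]`` recovers the original study identifier.
    """

    y: np.ndarray             # log10 chronic LOEC (log10 ug/L)
    x_size: np.ndarray        # log10 particle diameter (log10 um)
    x_media: np.ndarray       # freshwater 0, marine 1
    x_polymer: np.ndarray     # non-PS 0, PS 1
    ref_index: np.ndarray     # 0-based reference index
    ref_ids: tuple[str, ...]
    species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.y)
        for name in ("x_size", "x_media", "x_polymer", "ref_index"):
            if len(getattr(self, name)) != n:
                raise RecordValidationError(f"{name} length != n_obs {n}")
        for name in ("x_media", "x_polymer"):
            vals = np.asarray(getattr(self, name))
            if not np.isin(vals, (0, 1)).all():
                raise RecordValidationError(f"{name} must be 0/1")
        idx = np.asarray(self.ref_index)
        if n and (set(np.unique(idx)) != set(range(len(self.ref_ids)))):
            raise RecordValidationError("ref_index must cover 0..n_refs-1 with no gaps")

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_refs(self) -> int:
        return len(self.ref_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "y": self.y,
                "x_size": self.x_size,
                "x_media": self.x_media.astype(int),
                "x_polymer": self.x_polymer.astype(int),
                "ref_index": self.ref_index.astype(int),
                "reference_id": [self.ref_ids[j] for j in self.ref_index],
                "species_name": list(self.species) or [""] * self.n_obs,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PreparedDataset":
        ref_ids: list[str] = []
        seen: dict[str, int] = {}
        for rid in df["reference_id"]:
            if rid not in seen:
                seen[rid] = len(ref_ids)
                ref_ids.append(rid)
        return cls(
            y=df["y"].to_numpy(float),
            x_size=df["x_size"].to_numpy(float),
            x_media=df["x_media"].to_numpy(float),
            x_polymer=df["x_polymer"].to_numpy(float),
            ref_index=np.array([seen[r] for r in df["reference_id"]], dtype=int),
            ref_ids=tuple(ref_ids),
            species=tuple(df.get("species_name", pd.Series([""] * len(df)))),
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "PreparedDataset":
        return cls.from_frame(pd.read_csv(path, encoding="utf-8"))


def encode_predictors(
    records: Sequence[EffectRecord],
    ps_labels: Iterable[str] = DEFAULT_PS_LABELS,
) -> PreparedDataset:
    """Encode validated records into the regression design.

    Requires every record to carry a positive chronic LOEC and particle size
    and a resolved (non-brackish) medium; the filter/recategorise step must
    run first.
    """
    ps = {_norm(x) for x in ps_labels}
    y, xs, xm, xp, refs, species = [], [], [], [], [], []
    for rec in records:
        if rec.medium == "brackish":
            raise RecordValidationError(
                f"{rec.species_name}: brackish medium reached encoding; "
                "run filter_and_recategorize first"
            )
        if rec.chronic_loec is None or not rec.chronic_loec > 0:
            raise RecordValidationError(
                f"{rec.species_name}: chronic_loec missing or nonpositive"
            )
        if rec.size_um is None or not rec.size_um > 0:
            raise RecordValidationError(
                f"{rec.species_name}: size_um missing or nonpositive"
            )
        y.append(math.log10(rec.chronic_loec))
        xs.append(math.log10(rec.size_um))
        xm.append(1.0 if rec.medium == "marine" else 0.0)
        xp.append(1.0 if _norm(rec.polymer) in ps else 0.0)
        refs.append(rec.reference_id)
        species.append(rec.species_name)

    ref_ids: list[str] = []
    seen: dict[str, int] = {}
    for rid in refs:
        if rid not in seen:
            seen[rid] = len(ref_ids)
            ref_ids.append(rid)
    return PreparedDataset(
        y=np.array(y),
        x_size=np.array(xs),
        x_media=np.array(xm),
        x_polymer=np.array(xp),
        ref_index=np.array([seen[r] for r in refs], dtype=int),
        ref_ids=tuple(ref_ids),
        species=tuple(species),
    )


def preprocess_records(
    records: Sequence[EffectRecord],
    table: ExtrapolationTable | None = None,
    ps_labels: Iterable[str] = DEFAULT_PS_LABELS,
    freshwater_overrides: Iterable[str] = DEFAULT_FRESHWATER_OVERRIDES,
) -> PreparedDataset:
    """Full chain: convert -> filter/recategorise -> aggregate -> encode."""
    table = table or ExtrapolationTable.default()
    converted = [convert_to_chronic_loec(r, table) for r in records]
    filtered = filter_and_recategorize(converted, freshwater_overrides)
    aggregated = aggregate_geometric_mean(filtered, ps_labels)
    return encode_predictors(aggregated, ps_labels)
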