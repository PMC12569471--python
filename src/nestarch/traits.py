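"""Nest-trait encoding, validation and recoding.

Five traits describe a species' nest: whether it is in a cavity, its
structure (scrape/platform/cup/enclosed), its site, its mode of attachment,
and its height above ground. Height is recorded as a min/max range in
metres and is converted to a nominal trait by taking the geometric mean of
the range and binning it into ground (0 m), low, medium and high classes,
where the low/high cut points are the 10th and 90th percentiles of the
geometric-mean heights of the non-ground species. Rare site states are
merged into commoner ones before ordination: ant-nest sites (which in
practice sit in vegetation) become ``vegetation`` and water-body sites
become ``ground``.

Across the five recoded traits there are 2 + 4 + 4 + 3 + 4 = 17 states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

NEST_TYPES = ("cavity", "non_cavity")
STRUCTURES = ("scrape", "platform", "cup", "enclosed")
SITES = ("ground", "vegetation", "cliff", "underground", "water_body", "ant_nest")
SITES_RECODED = ("ground", "vegetation", "cliff", "underground")
ATTACHMENTS = ("basal", "lateral", "pensile")
HEIGHT_CLASSES = ("ground", "low", "medium", "high")
GROUPS = ("passerine", "landbird", "seabird")

#: nominal traits of a recoded record, with their closed state spaces
STATE_SPACE = {
    "nest_type": NEST_TYPES,
    "structure": STRUCTURES,
    "site": SITES_RECODED,
    "attachment": ATTACHMENTS,
    "height_class": HEIGHT_CLASSES,
}

NOMINAL_TRAITS = tuple(STATE_SPACE)

#: total number of trait states across the five nominal traits
N_TRAIT_STATES = sum(len(v) for v in STATE_SPACE.values())  # == 17


@dataclass(frozen=True)
class NestRecord:
    """Raw per-species nest description, as read from the input table."""

    species_id: str
    nest_type: str
    structure: str
    site: str
    attachment: str
    height_min_m: float
    height_max_m: float
    mass_min_g: float
    mass_max_g: float
    island_endemic: bool
    group: str = "landbird"

    def __post_init__(self) -> None:
        problems = validate_record_fields(self.__dict__)
        if problems:
            raise ValidationError(
                f"invalid NestRecord for {self.species_id!r}: " + "; ".join(problems)
            )


@dataclass(frozen=True)
class RecodedRecord:
    """Analysis-ready record: five nominal traits plus geometric means."""

    species_id: str
    nest_type: str
    structure: str
    site: str  # recoded: never water_body / ant_nest
    attachment: str
    height_class: str
    geo_mean_height_m: float
    geo_mean_mass_g: float

    def nominal_states(self) -> tuple[str, ...]:
        return tuple(getattr(self, t) for t in NOMINAL_TRAITS)


@dataclass(frozen=True)
class HeightThresholds:
    """10th/90th percentile cut points (metres) of non-ground nest heights."""

    p10_m: float
    p90_m: float

    def __post_init__(self) -> None:
        if not (0 < self.p10_m <= self.p90_m):
            raise ValidationError(
                f"invalid height thresholds: p10={self.p10_m}, p90={self.p90_m}"
            )


def validate_record_fields(row: dict) -> list[str]:
    """Return a list of problems with a raw record dict (empty if valid)."""
    problems = []
    checks = [
        ("nest_type", NEST_TYPES),
        ("structure", STRUCTURES),
        ("site", SITES),
        ("attachment", ATTACHMENTS),
        ("group", GROUPS),
    ]
    for field, states in checks:
        value = row.get(field)
        if value not in states:
            problems.append(f"{field}={value!r} not in {states}")
    for field in ("height_min_m", "height_max_m", "mass_min_g", "mass_max_g"):
        value = row.get(field)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            problems.append(f"{field} missing")
        elif not isinstance(value, (int, float)):
            problems.append(f"{field}={value!r} not numeric")
    if not problems:
        if row["height_min_m"] < 0:
            problems.append("height_min_m negative")
        if row["height_min_m"] > row["height_max_m"]:
            problems.append("height_min_m > height_max_m")
        if row["mass_min_g"] <= 0:
            problems.append("mass_min_g not positive")
        if row["mass_min_g"] > row["mass_max_g"]:
            problems.append("mass_min_g > mass_max_g")
    if not isinstance(row.get("island_endemic"), (bool, np.bool_)):
        problems.append(f"island_endemic={row.get('island_endemic')!r} not boolean")
    return problems


def geometric_mean(lo: float, hi: float) -> float:
    """sqrt(lo * hi) for a non-negative range; 0 annihilates the product."""
    if lo < 0 or hi < 0:
        raise ValidationError(f"negative range endpoint: ({lo}, {hi})")
    if lo > hi:
        raise ValidationError(f"range lower bound exceeds upper: ({lo}, {hi})")
    return math.sqrt(lo * hi)


def height_thresholds(gm_heights: Iterable[float]) -> HeightThresholds:
    """10th/90th percentiles of the strictly positive geometric-mean heights.

    Zeros (ground nesters) are excluded before computing percentiles;
    percentiles use linear interpolation between order statistics.
    """
    heights = np.asarray(list(gm_heights), dtype=float)
    if np.any(heights < 0):
        raise ValidationError("negative nest height")
    positive = heights[heights > 0]
    if positive.size < 2:
        raise ValidationError(
            f"need at least 2 elevated (height > 0) species, got {positive.size}"
        )
    p10, p90 = np.percentile(positive, [10, 90])
    return HeightThresholds(p10_m=float(p10), p90_m=float(p90))


def categorize_height(gm: float, t: HeightThresholds) -> str:
    """Bin a geometric-mean height: 0 -> ground, then (0,p10], (p10,p90], (p90,inf).

    Intervals are closed on the right, so a height equal to a cut point
    falls in the lower class.
    """
    if gm < 0:
        raise ValidationError(f"negative height {gm}")
    if gm == 0:
        return "ground"
    if gm <= t.p10_m:
        return "low"
    if gm <= t.p90_m:
        return "medium"
    return "high"


def recode_record(r: NestRecord, t: HeightThresholds) -> RecodedRecord:
    """Recode one record: merge rare sites, bin height, take geometric means."""
    site = {"ant_nest": "vegetation", "water_body": "ground"}.get(r.site, r.site)
    gm_height = geometric_mean(r.height_min_m, r.height_max_m)
    gm_mass = geometric_mean(r.mass_min_g, r.mass_max_g)
    return RecodedRecord(
        species_id=r.species_id,
        nest_type=r.nest_type,
        structure=r.structure,
        site=site,
        attachment=r.attachment,
        height_class=categorize_height(gm_height, t),
        geo_mean_height_m=gm_height,
        geo_mean_mass_g=gm_mass,
    )


def recode_table(
    records: Sequence[NestRecord],
) -> tuple[list[RecodedRecord], HeightThresholds]:
    """Recode a full table; thresholds are computed from the table itself."""
    t = height_thresholds(
        geometric_mean(r.height_min_m, r.height_max_m) for r in records
    )
    return [recode_record(r, t) for r in records], t


_NUMERIC_FIELDS = ("height_min_m", "height_max_m", "mass_min_g", "mass_max_g")


def read_nest_table(path) -> tuple[list[NestRecord], pd.DataFrame]:
    """Read a species x nest-trait CSV.

    Returns (valid records, rejects frame). Rows with missing or invalid
    fields are excluded, never imputed; the rejects frame lists each
    excluded species and the offending fields.
    """
    df = pd.read_csv(path)
    if "species_id" not in df.columns:
        raise ValidationError("nest table must have a 'species_id' column")
    records: list[NestRecord] = []
    rejects: list[dict] = []
    for _, row in df.iterrows():
        raw = row.to_dict()
        raw.setdefault("group", "landbird")
        for f in _NUMERIC_FIELDS:
            try:
                raw[f] = float(raw[f])
            except (TypeError, ValueError, KeyError):
                raw[f] = float("nan")
        raw["island_endemic"] = _parse_bool(raw.get("island_endemic"))
        problems = validate_record_fields(raw)
        if problems:
            rejects.append(
                {"species_id": raw.get("species_id"), "reason": "; ".join(problems)}
            )
            continue
        records.append(
            NestRecord(
                species_id=str(raw["species_id"]),
                nest_type=raw["nest_type"],
                structure=raw["structure"],
                site=raw["site"],
                attachment=raw["attachment"],
                height_min_m=raw["height_min_m"],
                height_max_m=raw["height_max_m"],
                mass_min_g=raw["mass_min_g"],
                mass_max_g=raw["mass_max_g"],
                island_endemic=raw["island_endemic"],
                group=raw["group"],
            )
        )
    ids = [r.species_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValidationError(f"duplicate species ids: {dupes}")
    return records, pd.DataFrame(rejects, columns=["species_id", "reason"])


def _parse_bool(value) -> object:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, str):
        v = value.strip().lower()
        if v in {"true", "1", "yes"}:
            return True
        if v in {"false", "0", "no"}:
            return False
    if isinstance(value, (int, np.integer)) and value in (0, 1):
        return bool(value)
    if isinstance(value, float) and value in (0.0, 1.0):
        return bool(value)
    return value  # left invalid; caught by validation


def records_to_frame(records: Sequence[NestRecord]) -> pd.DataFrame:
    """Raw records as a DataFrame (column order matches the CSV contract)."""
    return pd.DataFrame([r.__dict__ for r in records])


def recoded_to_frame(records: Sequence[RecodedRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def write_recoded(records: Sequence[RecodedRecord], path) -> None:
    recoded_to_frame(records).to_csv(path, index=False)
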