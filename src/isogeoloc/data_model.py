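"""Tissue isotope compilation: schema, validation, and unit conversions.

Human-tissue oxygen and strontium isotope records are compiled from many
studies, each reporting on its own terms. This module defines the canonical
record schema and normalizes every oxygen value onto a single currency —
the VSMOW scale, carbonate-equivalent for bioapatite — so downstream
calibration compares like with like.

Two fixed analytic conversions are applied at load time:

* VPDB -> VSMOW:  d18O_VSMOW = 1.03092 * d18O_VPDB + 30.92
* phosphate -> carbonate:  d18O_C = (d18O_P + 9.6849) / 1.0322

Tooth enamel records carry a mineralization-age group derived from the
dental element sampled (crown-formation windows 0-4, 0.5-6, 2.5-7 and
7.5-15 years); elements that cannot be resolved to a single window are
grouped as "Unknown".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Tissue",
    "Analyte",
    "OxygenScale",
    "OxygenPhase",
    "OriginStatus",
    "ToothGroup",
    "SampleRecord",
    "Dataset",
    "LoadReport",
    "SchemaConfig",
    "vpdb_to_vsmow",
    "vsmow_to_vpdb",
    "phosphate_to_carbonate",
    "carbonate_to_phosphate",
    "assign_tooth_group",
    "load_dataset",
    "write_dataset",
    "filter_multiple_origins",
    "great_circle_km",
]

# --- constants of the two reference-scale conversions ---
VPDB_TO_VSMOW_GAIN = 1.03092
VPDB_TO_VSMOW_OFFSET = 30.92
PHOSPHATE_CARBONATE_OFFSET = 9.6849
PHOSPHATE_CARBONATE_GAIN = 1.0322

#: value bounds used by record validation
SR_BOUNDS = (0.70, 0.75)
O_VSMOW_BOUNDS = (-30.0, 40.0)

EARTH_RADIUS_KM = 6371.0088

#: suffix appended to sample_id per analysis type so that repeat analyses
#: of one physical sample stay unique
ANALYSIS_SUFFIX = {"oxygen": "-O", "strontium": "-Sr", "phosphate": "-P"}

ADULT_AGE_YEARS = 18.0


class Tissue(str, Enum):
    HAIR = "hair"
    NAIL = "nail"
    BONE = "bone"
    TOOTH_ENAMEL = "tooth_enamel"


class Analyte(str, Enum):
    OXYGEN = "oxygen"
    STRONTIUM = "strontium"


class OxygenScale(str, Enum):
    VSMOW = "VSMOW"
    VPDB = "VPDB"
    NONE = "none"


class OxygenPhase(str, Enum):
    CARBONATE = "carbonate"
    PHOSPHATE = "phosphate"
    KERATIN = "keratin"
    NONE = "none"


class OriginStatus(str, Enum):
    KNOWN = "known"
    ASSUMED = "assumed"


class ToothGroup(str, Enum):
    """Crown-formation age windows for dental elements."""

    G0_4 = "G0_4"  # 0-4 y: first molars, central incisors
    G0P5_6 = "G0p5_6"  # 0.5-6 y: lateral incisors, canines
    G2P5_7 = "G2p5_7"  # 2.5-7 y: premolars, second molars
    G7P5_15 = "G7p5_15"  # 7.5-15 y: third molars
    UNKNOWN = "Unknown"
    NOT_TOOTH = "not_tooth"


class DataError(ValueError):
    """Invalid value or record in the compilation."""


class SchemaError(DataError):
    """Input table does not match the declared schema."""


def _require_finite(value: float, what: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise DataError(f"{what} must be finite, got {value!r}")
    return value


def vpdb_to_vsmow(value: float) -> float:
    """Convert a d18O value from the VPDB scale to VSMOW (per mil).

    Uses the standard linear relation
    ``d18O_VSMOW = 1.03092 * d18O_VPDB + 30.92``.
    """
    value = _require_finite(value, "d18O (VPDB)")
    return VPDB_TO_VSMOW_GAIN * value + VPDB_TO_VSMOW_OFFSET


def vsmow_to_vpdb(value: float) -> float:
    """Inverse of :func:`vpdb_to_vsmow`."""
    value = _require_finite(value, "d18O (VSMOW)")
    return (value - VPDB_TO_VSMOW_OFFSET) / VPDB_TO_VSMOW_GAIN


def phosphate_to_carbonate(value: float) -> float:
    """Convert an enamel phosphate d18O (VSMOW) to carbonate-equivalent.

    Uses ``d18O_C = (d18O_P + 9.6849) / 1.0322`` so that measured
    phosphate values can be pooled with the carbonate data.
    """
    value = _require_finite(value, "d18O phosphate")
    return (value + PHOSPHATE_CARBONATE_OFFSET) / PHOSPHATE_CARBONATE_GAIN


def carbonate_to_phosphate(value: float) -> float:
    """Inverse of :func:`phosphate_to_carbonate`."""
    value = _require_finite(value, "d18O carbonate")
    return value * PHOSPHATE_CARBONATE_GAIN - PHOSPHATE_CARBONATE_OFFSET


# --- dental element -> mineralization-age group ------------------------------

_TOOTH_VOCAB: dict[str, ToothGroup] = {
    "first molar": ToothGroup.G0_4,
    "1st molar": ToothGroup.G0_4,
    "m1": ToothGroup.G0_4,
    "central incisor": ToothGroup.G0_4,
    "i1": ToothGroup.G0_4,
    "lateral incisor": ToothGroup.G0P5_6,
    "i2": ToothGroup.G0P5_6,
    "canine": ToothGroup.G0P5_6,
    "c": ToothGroup.G0P5_6,
    "premolar": ToothGroup.G2P5_7,
    "first premolar": ToothGroup.G2P5_7,
    "second premolar": ToothGroup.G2P5_7,
    "1st premolar": ToothGroup.G2P5_7,
    "2nd premolar": ToothGroup.G2P5_7,
    "p3": ToothGroup.G2P5_7,
    "p4": ToothGroup.G2P5_7,
    "second molar": ToothGroup.G2P5_7,
    "2nd molar": ToothGroup.G2P5_7,
    "m2": ToothGroup.G2P5_7,
    "third molar": ToothGroup.G7P5_15,
    "3rd molar": ToothGroup.G7P5_15,
    "wisdom tooth": ToothGroup.G7P5_15,
    "m3": ToothGroup.G7P5_15,
}


def assign_tooth_group(element_label: str) -> ToothGroup:
    """Map a dental-element name to its crown-formation age group.

    The vocabulary resolves specific element names ("first molar",
    "canine", "third molar", "M2", ...). Ambiguous labels such as a bare
    "molar" or "incisor" — which span more than one formation window —
    return :attr:`ToothGroup.UNKNOWN`.
    """
    if not element_label or not element_label.strip():
        raise DataError("dental element label is empty")
    key = " ".join(element_label.lower().replace("_", " ").split())
    # strip side/arch qualifiers that do not affect the formation window
    for noise in ("upper ", "lower ", "left ", "right ", "maxillary ", "mandibular ", "deciduous "):
        key = key.replace(noise, "")
    return _TOOTH_VOCAB.get(key.strip(), ToothGroup.UNKNOWN)


# --- records ------------------------------------------------------------------


@dataclass(frozen=True)
class SampleRecord:
    """One tissue isotope measurement with site and provenance metadata."""

    sample_id: str
    site_id: str
    longitude: float
    latitude: float
    country: str
    tissue: Tissue
    analyte: Analyte
    value: float
    oxygen_scale: OxygenScale = OxygenScale.NONE
    oxygen_phase: OxygenPhase = OxygenPhase.NONE
    calibration_scale: str = ""
    origin_status: OriginStatus = OriginStatus.KNOWN
    study_id: str = ""
    tooth_element: str = ""
    tooth_group: ToothGroup = ToothGroup.NOT_TOOTH
    sex: str = "unknown"
    age_class: str = "unknown"

    def validate(self) -> None:
        """Raise :class:`DataError` on any violated record invariant."""
        if not math.isfinite(self.value):
            raise DataError(f"{self.sample_id}: non-finite value")
        if not (-90.0 <= self.latitude <= 90.0):
            raise DataError(f"{self.sample_id}: coordinate out of range (lat {self.latitude})")
        if not (-180.0 <= self.longitude <= 180.0):
            raise DataError(f"{self.sample_id}: coordinate out of range (lon {self.longitude})")
        if self.analyte is Analyte.STRONTIUM:
            if not (SR_BOUNDS[0] < self.value < SR_BOUNDS[1]):
                raise DataError(f"{self.sample_id}: 87Sr/86Sr {self.value} outside {SR_BOUNDS}")
            if self.oxygen_scale is not OxygenScale.NONE:
                raise DataError(f"{self.sample_id}: strontium record carries an oxygen scale")
        else:
            if self.oxygen_scale is OxygenScale.NONE:
                raise DataError(f"{self.sample_id}: oxygen record lacks a reference scale")
            if self.oxygen_scale is OxygenScale.VSMOW and not (
                O_VSMOW_BOUNDS[0] < self.value < O_VSMOW_BOUNDS[1]
            ):
                raise DataError(
                    f"{self.sample_id}: d18O {self.value} outside plausible VSMOW range"
                )
        is_tooth = self.tissue is Tissue.TOOTH_ENAMEL
        if (self.tooth_group is ToothGroup.NOT_TOOTH) == is_tooth:
            raise DataError(
                f"{self.sample_id}: tooth_group {self.tooth_group.value} "
                f"inconsistent with tissue {self.tissue.value}"
            )
        if self.sex not in ("M", "F", "unknown"):
            raise DataError(f"{self.sample_id}: sex must be M/F/unknown")
        if self.age_class not in ("adult", "nonadult", "unknown"):
            raise DataError(f"{self.sample_id}: age_class must be adult/nonadult/unknown")


#: canonical column order of the on-disk CSV
CANONICAL_COLUMNS = [f.name for f in fields(SampleRecord)]


@dataclass
class Dataset:
    """Ordered collection of validated :class:`SampleRecord`."""

    records: list[SampleRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate sample_id after analysis suffixing: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, predicate: Callable[[SampleRecord], bool]) -> "Dataset":
        return Dataset([r for r in self.records if predicate(r)], provenance=self.provenance)

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of lon/lat."""
        return np.array([[r.longitude, r.latitude] for r in self.records], dtype=float)

    def values(self) -> np.ndarray:
        return np.array([r.value for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = {}
            for f in fields(SampleRecord):
                v = getattr(r, f.name)
                d[f.name] = v.value if isinstance(v, Enum) else v
            rows.append(d)
        return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


@dataclass
class LoadReport:
    """Row-level accounting of a compilation load."""

    n_read: int = 0
    n_kept: int = 0
    n_converted_vpdb: int = 0
    n_converted_phosphate: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    row_errors: list[dict] = field(default_factory=list)

    def drop(self, row_index: int, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1
        self.row_errors.append({"row": int(row_index), "reason": reason})

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_read": self.n_read,
                "n_kept": self.n_kept,
                "n_converted_vpdb": self.n_converted_vpdb,
                "n_converted_phosphate": self.n_converted_phosphate,
                "dropped": self.dropped,
                "row_errors": self.row_errors,
            },
            indent=2,
        )


@dataclass
class SchemaConfig:
    """Maps source CSV headers onto canonical fields.

    The deposited compilations in this domain do not share a header
    convention, so the adapter is explicit: ``columns`` maps canonical
    field name -> source column name. Unmapped canonical fields fall back
    to the same name. ``apply_suffix`` appends the analysis-type code
    ("-O"/"-Sr") to sample ids as in multi-analysis compilations.
    """

    columns: dict[str, str] = field(default_factory=dict)
    apply_suffix: bool = True

    def source_column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    @classmethod
    def from_file(cls, path) -> "SchemaConfig":
        """Read a ``key = value`` config; key ``apply_suffix`` is boolean."""
        columns: dict[str, str] = {}
        apply_suffix = True
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key == "apply_suffix":
                    apply_suffix = val.lower() in ("1", "true", "yes")
                else:
                    columns[key] = val
        return cls(columns=columns, apply_suffix=apply_suffix)


_MANDATORY = ["sample_id", "site_id", "longitude", "latitude", "tissue", "analyte", "value"]

_ENUM_FIELDS = {
    "tissue": Tissue,
    "analyte": Analyte,
    "oxygen_scale": OxygenScale,
    "oxygen_phase": OxygenPhase,
    "origin_status": OriginStatus,
    "tooth_group": ToothGroup,
}

_DEFAULTS = {
    "country": "",
    "oxygen_scale": "none",
    "oxygen_phase": "none",
    "calibration_scale": "",
    "origin_status": "known",
    "study_id": "",
    "tooth_element": "",
    "tooth_group": "",
    "sex": "unknown",
    "age_class": "unknown",
}


def _bin_age(raw: str) -> str:
    """Adults are 18 y and older; numeric ages are binned at load."""
    raw = str(raw).strip()
    if raw in ("adult", "nonadult", "unknown", ""):
        return raw or "unknown"
    try:
        age = float(raw)
    except ValueError:
        return "unknown"
    return "adult" if age >= ADULT_AGE_YEARS else "nonadult"


def _parse_row(row: Mapping, cfg: SchemaConfig, report: LoadReport) -> SampleRecord:
    def get(canonical: str, default=None):
        col = cfg.source_column(canonical)
        if col in row and not pd.isna(row[col]) and str(row[col]).strip() != "":
            return str(row[col]).strip()
        if default is not None:
            return default
        raise DataError(f"missing value for {canonical}")

    try:
        lon = float(get("longitude"))
        lat = float(get("latitude"))
    except (ValueError, DataError) as exc:
        raise DataError(f"unparseable coordinate ({exc})") from exc
    if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
        raise DataError("coordinate out of range")

    kwargs: dict = {"longitude": lon, "latitude": lat}
    kwargs["sample_id"] = get("sample_id")
    kwargs["site_id"] = get("site_id")
    kwargs["country"] = get("country", _DEFAULTS["country"])
    for name, enum_cls in _ENUM_FIELDS.items():
        raw = get(name, _DEFAULTS.get(name, "")) if name not in ("tissue", "analyte") else get(name)
        if name == "tooth_group" and raw == "":
            continue  # derived below
        try:
            kwargs[name] = enum_cls(raw)
        except ValueError as exc:
            raise DataError(f"invalid {name} {raw!r}") from exc
    try:
        value = float(get("value"))
    except ValueError as exc:
        raise DataError(f"unparseable value ({exc})") from exc

    kwargs["calibration_scale"] = get("calibration_scale", _DEFAULTS["calibration_scale"])
    kwargs["study_id"] = get("study_id", _DEFAULTS["study_id"])
    kwargs["tooth_element"] = get("tooth_element", _DEFAULTS["tooth_element"])
    sex = get("sex", "unknown")
    kwargs["sex"] = sex if sex in ("M", "F") else "unknown"
    kwargs["age_class"] = _bin_age(get("age_class", "unknown"))

    # normalize oxygen to VSMOW carbonate-equivalent
    if kwargs["analyte"] is Analyte.OXYGEN:
        if kwargs["oxygen_scale"] is OxygenScale.VPDB:
            value = vpdb_to_vsmow(value)
            kwargs["oxygen_scale"] = OxygenScale.VSMOW
            report.n_converted_vpdb += 1
        if kwargs["oxygen_phase"] is OxygenPhase.PHOSPHATE:
            value = phosphate_to_carbonate(value)
            kwargs["oxygen_phase"] = OxygenPhase.CARBONATE
            report.n_converted_phosphate += 1
        if kwargs["oxygen_phase"] is OxygenPhase.NONE:
            kwargs["oxygen_phase"] = (
                OxygenPhase.KERATIN
                if kwargs["tissue"] in (Tissue.HAIR, Tissue.NAIL)
                else OxygenPhase.CARBONATE
            )
    kwargs["value"] = value

    # tooth group: taken from the file when present, else derived from element
    if "tooth_group" not in kwargs:
        if kwargs["tissue"] is Tissue.TOOTH_ENAMEL:
            kwargs["tooth_group"] = (
                assign_tooth_group(kwargs["tooth_element"])
                if kwargs["tooth_element"]
                else ToothGroup.UNKNOWN
            )
        else:
            kwargs["tooth_group"] = ToothGroup.NOT_TOOTH

    if cfg.apply_suffix:
        suffix = ANALYSIS_SUFFIX[kwargs["analyte"].value]
        if not kwargs["sample_id"].endswith(suffix):
            kwargs["sample_id"] = kwargs["sample_id"] + suffix

    record = SampleRecord(**kwargs)
    record.validate()
    return record


def load_dataset(path, schema: SchemaConfig | None = None) -> tuple[Dataset, LoadReport]:
    """Load and validate a compilation CSV.

    Every row becomes a validated :class:`SampleRecord`; oxygen values are
    normalized to VSMOW carbonate-equivalent, applying the VPDB and
    phosphate conversions where the declared scale/phase demand it. Rows
    violating an invariant are dropped and accounted for in the returned
    :class:`LoadReport` — a bad row never aborts the load.

    Raises :class:`SchemaError` if a mandatory column is absent.
    """
    cfg = schema or SchemaConfig()
    frame = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing = [c for c in _MANDATORY if cfg.source_column(c) not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    report = LoadReport(n_read=len(frame))
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        try:
            rec = _parse_row(row, cfg, report)
        except DataError as exc:
            report.drop(idx, str(exc))
            continue
        if rec.sample_id in seen:
            raise DataError(f"sample_id collision after suffixing: {rec.sample_id!r}")
        seen.add(rec.sample_id)
        records.append(rec)
    report.n_kept = len(records)
    return Dataset(records, provenance=str(path)), report


def write_dataset(dataset: Dataset, path) -> None:
    """Write the canonical CSV (fixed column order, UTF-8, '.' decimals)."""
    dataset.to_frame().to_csv(path, index=False, encoding="utf-8")


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine great-circle distance in km on the WGS84 mean sphere."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def filter_multiple_origins(
    candidates: Mapping[str, Sequence[tuple[float, float]]],
    max_separation_km: float = 25.0,
) -> set[str]:
    """Identify records whose listed origins are geographically consistent.

    ``candidates`` maps sample_id -> list of (lon, lat) origins from the
    residence history. Samples whose origins all fall within
    ``max_separation_km`` of each other (default 25 km, the midpoint of
    the usual 20-30 km proximity window) are accepted; movers are dropped.
    Returns the set of accepted sample_ids.
    """
    keep: set[str] = set()
    for sid, pts in candidates.items():
        ok = True
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = float(
                    great_circle_km(pts[i][0], pts[i][1], pts[j][0], pts[j][1])
                )
                if d > max_separation_km:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            keep.add(sid)
    return keep
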