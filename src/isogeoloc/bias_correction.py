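"""Systematic-bias removal: residual group corrections and scale transforms.

Two correction mechanisms:

* **Residual bias table** — the mean calibration residual of each group
  (study, or tooth mineralization-age group) is subtracted from that
  group's published values, removing systematic inter-group offsets while
  leaving within-group structure intact. Corrections are estimated and
  applied on the same dataset by default (a leave-group-out mode exists
  for honesty checks).

* **Reference-scale transform** — keratin d18O data calibrated against
  different in-house reference materials are mapped onto a common VSMOW
  realization through per-scale linear (gain, offset) coefficients
  supplied as configuration. Unknown scale labels raise rather than pass
  through silently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .calibration import CalibrationFit
from .data_model import Dataset, SampleRecord

logger = logging.getLogger("isogeoloc")

__all__ = [
    "BiasTable",
    "ScaleTransform",
    "build_bias_table",
    "apply_bias_correction",
    "transform_reference_scale",
]


class UnknownScaleError(KeyError):
    """A calibration-scale label has no transform coefficients."""


@dataclass
class BiasTable:
    """group_id -> correction (the group's mean residual, tissue units)."""

    corrections: dict[str, float]
    grouping_name: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {"grouping": self.grouping_name, "corrections": self.corrections}, indent=2
        )

    @classmethod
    def from_json(cls, text: str) -> "BiasTable":
        d = json.loads(text)
        return cls(corrections={k: float(v) for k, v in d["corrections"].items()},
                   grouping_name=d.get("grouping", ""))


def build_bias_table(
    fit: CalibrationFit,
    grouping: Mapping[str, str],
    leave_group_out: bool = False,
) -> BiasTable:
    """Estimate per-group corrections as mean calibration residuals.

    With ``leave_group_out`` the correction for group g is instead the
    group's mean offset relative to a fit excluding g's own pull on the
    global mean residual — a cheap honesty check, off by default.
    """
    missing = [sid for sid in fit.record_ids if sid not in grouping]
    if missing:
        raise ValueError(f"grouping does not cover fit records: {missing[:5]}")
    by_group: dict[str, list[float]] = {}
    for sid, r in zip(fit.record_ids, fit.residuals):
        by_group.setdefault(str(grouping[sid]), []).append(float(r))
    corrections: dict[str, float] = {}
    for g, res in sorted(by_group.items()):
        if not res:
            logger.warning("group %s has no records; omitted from bias table", g)
            continue
        if leave_group_out:
            others = [r for gg, rr in by_group.items() if gg != g for r in rr]
            baseline = float(np.mean(others)) if others else 0.0
            corrections[g] = float(np.mean(res)) - baseline
        else:
            corrections[g] = float(np.mean(res))
    return BiasTable(corrections=corrections)


def apply_bias_correction(
    dataset: Dataset,
    bias: BiasTable,
    grouping: Mapping[str, str],
    uncorrected_groups: Sequence[str] = ("Unknown",),
) -> Dataset:
    """Subtract each record's group correction from its value.

    Records whose group is absent from the table (or listed in
    ``uncorrected_groups``, default the heterogeneous "Unknown" tooth
    group) pass through unchanged with a log entry. The operation is only
    idempotent if the bias table is rebuilt from a refit.
    """
    skip = set(uncorrected_groups)
    out: list[SampleRecord] = []
    n_unmatched = 0
    for rec in dataset:
        g = grouping.get(rec.sample_id)
        if g is None or g in skip or g not in bias.corrections:
            n_unmatched += 1
            out.append(rec)
            continue
        out.append(replace(rec, value=rec.value - bias.corrections[g]))
    if n_unmatched:
        logger.info("bias correction left %d record(s) unchanged (no matching group)", n_unmatched)
    return Dataset(out, provenance=dataset.provenance + " [bias-corrected]")


@dataclass
class ScaleTransform:
    """Per-scale linear maps onto the common VSMOW realization.

    ``table[label] = (gain, offset)``: a value v reported on ``label``'s
    scale reads ``gain * v + offset`` on the common frame. Transforming
    between two labels composes through the common frame.
    """

    table: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, (gain, offset) in self.table.items():
            if gain <= 0:
                raise ValueError(f"scale {label!r}: gain must be positive")

    def to_common(self, values, label: str) -> np.ndarray:
        if label not in self.table:
            raise UnknownScaleError(
                f"calibration scale {label!r} has no transform coefficients; "
                "samples on undetermined scales must be excluded"
            )
        gain, offset = self.table[label]
        return gain * np.asarray(values, dtype=float) + offset

    def from_common(self, values, label: str) -> np.ndarray:
        if label not in self.table:
            raise UnknownScaleError(f"calibration scale {label!r} unknown")
        gain, offset = self.table[label]
        return (np.asarray(values, dtype=float) - offset) / gain

    @classmethod
    def from_json(cls, text: str) -> "ScaleTransform":
        d = json.loads(text)
        return cls(table={k: (float(v[0]), float(v[1])) for k, v in d.items()})

    def to_json(self) -> str:
        return json.dumps({k: list(v) for k, v in self.table.items()}, indent=2)


def transform_reference_scale(
    values, from_label: str, to_label: str, table: ScaleTransform
) -> np.ndarray:
    """Re-express values from one calibration scale on another.

    Same-label transforms are the identity; A->B then B->A round-trips to
    the original values. Unknown labels raise :class:`UnknownScaleError`.
    """
    values = np.asarray(values, dtype=float)
    if from_label == to_label:
        if from_label not in table.table:
            raise UnknownScaleError(f"calibration scale {from_label!r} unknown")
        return values.copy()
    return table.from_common(table.to_common(values, from_label), to_label)
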