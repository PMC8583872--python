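"""Cohort CSV readers/writers and simulation-config (de)serialization.

Two cohort schemas, both plain UTF-8 comma-separated text with a mandatory
header row and one row per matched subject-week pair:

* **item_level** — ``subject_id, week`` followed by one column per item,
  prefixed by scale: ``rpq_headache ... scat_nervous_anxious`` (16 + 22
  severity columns).
* **score_level** — ``subject_id, week, rpq_total, rpq_count, scat_total,
  scat_count`` plus per-domain subscore columns (``rpq_somatic``, ...,
  ``scat_unclassified``).

The first line is a comment carrying the schema version and scoring
conventions, e.g.::

    # rpqscat schema_version=1 format=item_level fatigue_in_somatic=true recode_mild=false

so that ``read(write(x)) == x`` holds for both formats. Files without the
comment are accepted; the format is then inferred from the columns and
default conventions are assumed. Unknown columns are preserved as
passthrough metadata, never dropped silently. A missing assessment is an
absent row — blank severities are a validation error naming the cell.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .errors import ValidationError
from .scales import (
    Assessment,
    Domain,
    PairedRecord,
    ScaleId,
    ScoreSummary,
    get_scale,
    score_assessment,
)
from .simulate import DropoutRule, ItemParams, SimulationConfig, calibrate_defaults

__all__ = [
    "CohortTable",
    "read_cohort",
    "write_cohort",
    "load_sim_config",
    "dump_sim_config",
]

SCHEMA_VERSION = 1

_KEY_COLUMNS = ["subject_id", "week"]


def _item_columns() -> list[str]:
    cols = []
    for sid in ScaleId:
        cols += [f"{sid.value}_{i}" for i in get_scale(sid).item_ids]
    return cols


def _score_columns() -> list[str]:
    cols = []
    for sid in ScaleId:
        cols += [f"{sid.value}_total", f"{sid.value}_count"]
    for sid in ScaleId:
        cols += [f"{sid.value}_{d.value}" for d in Domain]
    return cols


@dataclass
class CohortTable:
    """A typed, validated paired cohort plus provenance metadata."""

    format: str  # "item_level" | "score_level"
    pairs: list[PairedRecord]
    provenance: Optional[str] = None
    schema_version: int = SCHEMA_VERSION
    fatigue_in_somatic: bool = True
    recode_mild: bool = False
    extra: Optional[pd.DataFrame] = None  # passthrough columns, if any


def _parse_header_comment(line: str) -> dict[str, str]:
    fields = {}
    for token in line.lstrip("#").split():
        if "=" in token:
            k, v = token.split("=", 1)
            fields[k] = v
    return fields


def _bool(s: str) -> bool:
    return s.lower() in ("1", "true", "yes")


def read_cohort(
    path: Union[str, Path, _io.TextIOBase], format: Optional[str] = None
) -> CohortTable:
    """Read a cohort CSV in either schema, validating every cell.

    ``format`` may be given explicitly; otherwise it is taken from the
    header comment or inferred from the columns.
    """
    provenance = str(path) if isinstance(path, (str, Path)) else "<stream>"
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()
    meta: dict[str, str] = {}
    if text.startswith("#"):
        meta = _parse_header_comment(text.splitlines()[0])
    df = pd.read_csv(_io.StringIO(text), comment="#", dtype={"subject_id": str})

    fmt = format or meta.get("format")
    if fmt is None:
        fmt = "item_level" if any(c in df.columns for c in _item_columns()) else "score_level"
    if fmt not in ("item_level", "score_level"):
        raise ValidationError(f"unknown cohort format {fmt!r}")
    fatigue = _bool(meta.get("fatigue_in_somatic", "true"))
    recode = _bool(meta.get("recode_mild", "false"))
    version = int(meta.get("schema_version", SCHEMA_VERSION))

    required = _KEY_COLUMNS + (
        _item_columns()
        if fmt == "item_level"
        else [f"{s.value}_{f}" for s in ScaleId for f in ("total", "count")]
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{provenance}: missing required columns {missing}")
    extra_cols = [c for c in df.columns if c not in required and c not in _score_columns()]
    extra = df[_KEY_COLUMNS + extra_cols].copy() if extra_cols else None

    pairs = (
        _pairs_from_item_level(df, provenance, fatigue, recode)
        if fmt == "item_level"
        else _pairs_from_score_level(df, provenance, fatigue)
    )
    return CohortTable(
        format=fmt,
        pairs=pairs,
        provenance=provenance,
        schema_version=version,
        fatigue_in_somatic=fatigue,
        recode_mild=recode,
        extra=extra,
    )


def _cell_int(row_idx: int, col: str, value, lo: int, hi: int, provenance: str) -> int:
    try:
        # reject NaN/blank and non-integral floats
        f = float(value)
        i = int(f)
        if f != i:
            raise ValueError
    except (TypeError, ValueError):
        raise ValidationError(
            f"{provenance}: row {row_idx}, column '{col}': "
            f"unparseable value {value!r}"
        ) from None
    if not lo <= i <= hi:
        raise ValidationError(
            f"{provenance}: row {row_idx}, column '{col}': "
            f"value {i} outside [{lo}, {hi}]"
        )
    return i


def _pairs_from_item_level(
    df: pd.DataFrame, provenance: str, fatigue: bool, recode: bool
) -> list[PairedRecord]:
    pairs = []
    for idx, row in df.iterrows():
        week = _cell_int(idx, "week", row["week"], 1, 10**6, provenance)
        assessments = {}
        for sid in ScaleId:
            scale = get_scale(sid)
            sev = tuple(
                _cell_int(
                    idx, f"{sid.value}_{i}", row[f"{sid.value}_{i}"],
                    0, scale.item_max, provenance,
                )
                for i in scale.item_ids
            )
            assessments[sid] = Assessment(str(row["subject_id"]), week, sid, sev)
        pairs.append(
            PairedRecord(
                subject_id=str(row["subject_id"]),
                week=week,
                rpq=score_assessment(assessments[ScaleId.RPQ], fatigue, recode),
                scat=score_assessment(assessments[ScaleId.SCAT], fatigue),
                rpq_assessment=assessments[ScaleId.RPQ],
                scat_assessment=assessments[ScaleId.SCAT],
            )
        )
    return pairs


def _pairs_from_score_level(
    df: pd.DataFrame, provenance: str, fatigue: bool
) -> list[PairedRecord]:
    has_domains = all(c in df.columns for c in _score_columns())
    pairs = []
    for idx, row in df.iterrows():
        week = _cell_int(idx, "week", row["week"], 1, 10**6, provenance)
        summaries = {}
        for sid in ScaleId:
            scale = get_scale(sid)
            total = _cell_int(
                idx, f"{sid.value}_total", row[f"{sid.value}_total"],
                0, scale.max_total, provenance,
            )
            count = _cell_int(
                idx, f"{sid.value}_count", row[f"{sid.value}_count"],
                0, scale.n_items, provenance,
            )
            domain_scores = None
            if has_domains:
                domain_scores = {
                    d: _cell_int(
                        idx, f"{sid.value}_{d.value}", row[f"{sid.value}_{d.value}"],
                        0, scale.max_total, provenance,
                    )
                    for d in Domain
                }
            try:
                summaries[sid] = ScoreSummary(
                    scale_id=sid,
                    total=total,
                    symptom_count=count,
                    domain_scores=domain_scores,
                    fatigue_in_somatic=fatigue,
                )
            except ValidationError as exc:
                raise ValidationError(f"{provenance}: row {idx}: {exc}") from None
        pairs.append(
            PairedRecord(
                subject_id=str(row["subject_id"]),
                week=week,
                rpq=summaries[ScaleId.RPQ],
                scat=summaries[ScaleId.SCAT],
            )
        )
    return pairs


def write_cohort(
    path: Union[str, Path, _io.TextIOBase],
    pairs: Sequence[PairedRecord],
    format: str = "item_level",
    fatigue_in_somatic: bool = True,
    recode_mild: bool = False,
) -> None:
    """Write matched pairs to CSV in the requested schema."""
    if format == "item_level":
        if any(not p.has_items for p in pairs):
            raise ValidationError(
                "item_level output needs item-level assessments on every pair"
            )
        rows = []
        for p in pairs:
            row: dict = {"subject_id": p.subject_id, "week": p.week}
            for sid, a in ((ScaleId.RPQ, p.rpq_assessment), (ScaleId.SCAT, p.scat_assessment)):
                row.update(
                    {f"{sid.value}_{i}": s for i, s in zip(get_scale(sid).item_ids, a.severities)}
                )
            rows.append(row)
        columns = _KEY_COLUMNS + _item_columns()
    elif format == "score_level":
        with_domains = all(
            p.rpq.domain_scores is not None and p.scat.domain_scores is not None
            for p in pairs
        )
        rows = []
        for p in pairs:
            row = {"subject_id": p.subject_id, "week": p.week}
            for sid, s in ((ScaleId.RPQ, p.rpq), (ScaleId.SCAT, p.scat)):
                row[f"{sid.value}_total"] = s.total
                row[f"{sid.value}_count"] = s.symptom_count
                if with_domains:
                    row.update(
                        {f"{sid.value}_{d.value}": s.domain_scores[d] for d in Domain}
                    )
            rows.append(row)
        columns = _KEY_COLUMNS + [
            c for c in _score_columns() if with_domains or c.endswith(("_total", "_count"))
        ]
    else:
        raise ValidationError(f"unknown cohort format {format!r}")

    header = (
        f"# rpqscat schema_version={SCHEMA_VERSION} format={format} "
        f"fatigue_in_somatic={str(fatigue_in_somatic).lower()} "
        f"recode_mild={str(recode_mild).lower()}\n"
    )
    df = pd.DataFrame(rows, columns=columns)
    if isinstance(path, (str, Path)):
        with open(path, "w", newline="") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    else:
        path.write(header)
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Simulation config YAML


def dump_sim_config(config: SimulationConfig, path: Union[str, Path]) -> None:
    """Serialize a simulation config to YAML (schema-versioned)."""
    data = {
        "schema_version": SCHEMA_VERSION,
        "n_subjects": config.n_subjects,
        "week_schedule": list(config.week_schedule),
        "seed": config.seed,
        "baseline_mean": config.baseline_mean,
        "baseline_sd": config.baseline_sd,
        "recovery_rate_mean": config.recovery_rate_mean,
        "recovery_rate_sd": config.recovery_rate_sd,
        "visit_noise": config.visit_noise,
        "cross_scale_noise": config.cross_scale_noise,
        "fatigue_in_somatic": config.fatigue_in_somatic,
        "dropout": {
            "leave_when_asymptomatic": config.dropout.leave_when_asymptomatic,
            "weekly_attrition": config.dropout.weekly_attrition,
        },
        "item_params": {
            sid.value: {
                item_id: {
                    "discrimination": p.discrimination,
                    "thresholds": list(p.thresholds),
                }
                for item_id, p in params.items()
            }
            for sid, params in config.item_params.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_sim_config(path: Union[str, Path], **overrides) -> SimulationConfig:
    """Load a simulation config from YAML.

    Omitted fields fall back to the shipped calibrated defaults; keyword
    overrides (e.g. ``seed=...``) win over the file.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    data.pop("schema_version", None)
    if "dropout" in data:
        data["dropout"] = DropoutRule(**data["dropout"])
    if "week_schedule" in data:
        data["week_schedule"] = tuple(data["week_schedule"])
    if "item_params" in data:
        data["item_params"] = {
            ScaleId(sid): {
                item_id: ItemParams(
                    discrimination=p["discrimination"],
                    thresholds=tuple(p["thresholds"]),
                )
                for item_id, p in params.items()
            }
            for sid, params in data["item_params"].items()
        }
    data.update(overrides)
    unknown = set(data) - set(SimulationConfig.__dataclass_fields__)
    if unknown:
        raise ValidationError(f"unknown simulation config fields: {sorted(unknown)}")
    return calibrate_defaults(**data)
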