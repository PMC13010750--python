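"""Table reading/merging, complete-case filtering, labeled CSV output and
RDF Turtle export.

The canonical flat schema is one row per patient:
``patient_id, age, sex, ethnicity, <6 comorbidity flags>,
left_air_500..right_air_8000, left_bone_500..right_bone_8000,
left_tymp_abnormal, right_tymp_abnormal`` followed, for labeled tables, by
``Has_Type, Has_Severity, Has_Laterality, recommendedTreatment`` and the
SNOMED concept-id columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from rdflib import RDF, Graph, Literal, Namespace
from rdflib.namespace import XSD

from .errors import ConfigurationError, SchemaError
from .features import PatientRecord
from .rules import SemanticLabels
from .snomed import CONCEPT_COLUMNS, LABEL_COLUMNS, annotate_labels
from .vocab import AUDIOMETRIC_FREQS, COMORBIDITY_FLAGS

logger = logging.getLogger(__name__)

META_COLUMNS = ("patient_id", "age", "sex", "ethnicity") + COMORBIDITY_FLAGS
THRESHOLD_COLUMNS = tuple(
    f"{side}_{kind}_{f}"
    for side in ("left", "right")
    for kind in ("air", "bone")
    for f in AUDIOMETRIC_FREQS
)
TYMP_COLUMNS = ("left_tymp_abnormal", "right_tymp_abnormal")
AIR_COLUMNS = tuple(c for c in THRESHOLD_COLUMNS if "_air_" in c)
RECORD_COLUMNS = META_COLUMNS + THRESHOLD_COLUMNS + TYMP_COLUMNS
LABEL_COLUMN_ORDER = tuple(LABEL_COLUMNS[d] for d in ("type", "severity", "laterality", "treatment"))

#: cell values treated as missing on input, besides empty cells.
MISSING_SENTINELS = ("", ".", "NA", "NaN")


@dataclass(frozen=True)
class TableSpec:
    """One input CSV: its path, identifier column and column mapping."""

    path: str
    id_column: str = "patient_id"
    column_map: Dict[str, str] = field(default_factory=dict)


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "age": r.age, "sex": r.sex,
               "ethnicity": r.ethnicity}
        for flag in COMORBIDITY_FLAGS:
            row[flag] = int(bool(getattr(r, flag)))
        for side in ("left", "right"):
            air, bone = r.air(side), r.bone(side)
            for f in AUDIOMETRIC_FREQS:
                row[f"{side}_air_{f}"] = air.get(f)
                row[f"{side}_bone_{f}"] = None if bone is None else bone.get(f)
            tymp = r.tymp_abnormal(side)
            row[f"{side}_tymp_abnormal"] = None if tymp is None else int(tymp)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


def _cell(row, col):
    if col not in row:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    if isinstance(v, str) and v.strip() in MISSING_SENTINELS:
        return None
    return v


def frame_to_records(df: pd.DataFrame) -> List[PatientRecord]:
    missing_meta = [c for c in META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise SchemaError(f"table lacks required columns: {missing_meta}")
    records = []
    for _, row in df.iterrows():
        kwargs = {
            "patient_id": str(row["patient_id"]),
            "age": float(row["age"]),
            "sex": str(row["sex"]),
            "ethnicity": str(row["ethnicity"]),
        }
        for flag in COMORBIDITY_FLAGS:
            kwargs[flag] = bool(int(row[flag]))
        for side in ("left", "right"):
            air, bone = {}, {}
            for f in AUDIOMETRIC_FREQS:
                v = _cell(row, f"{side}_air_{f}")
                if v is not None:
                    air[f] = float(v)
                v = _cell(row, f"{side}_bone_{f}")
                if v is not None:
                    bone[f] = float(v)
            kwargs[f"{side}_air"] = air
            kwargs[f"{side}_bone"] = bone or None
            tymp = _cell(row, f"{side}_tymp_abnormal")
            kwargs[f"{side}_tymp_abnormal"] = None if tymp is None else bool(int(float(tymp)))
        records.append(PatientRecord(**kwargs))
    return records


def read_and_merge(specs: Sequence[TableSpec]) -> List[PatientRecord]:
    """Inner-join the given tables on the patient identifier.

    One record per identifier present in *every* table.  Duplicate
    identifiers within a table and missing id columns raise
    :class:`SchemaError`; columns outside the canonical schema are ignored
    with a logged warning.
    """
    if not specs:
        raise ConfigurationError("no input tables given")
    merged: Optional[pd.DataFrame] = None
    for spec in specs:
        df = pd.read_csv(spec.path, dtype={spec.id_column: str})
        if spec.column_map:
            df = df.rename(columns=spec.column_map)
        id_col = spec.column_map.get(spec.id_column, spec.id_column)
        if id_col != "patient_id" and id_col in df.columns:
            df = df.rename(columns={id_col: "patient_id"})
        if "patient_id" not in df.columns:
            raise SchemaError(f"{spec.path}: id column {spec.id_column!r} not found")
        dupes = df["patient_id"][df["patient_id"].duplicated()].unique()
        if len(dupes):
            raise SchemaError(
                f"{spec.path}: duplicate patient identifier(s): {sorted(map(str, dupes))}"
            )
        known = set(RECORD_COLUMNS) | set(LABEL_COLUMN_ORDER) | set(CONCEPT_COLUMNS.values())
        unmapped = [c for c in df.columns if c not in known]
        if unmapped:
            logger.warning("%s: ignoring unmapped column(s): %s", spec.path, unmapped)
            df = df.drop(columns=unmapped)
        merged = df if merged is None else merged.merge(
            df, on="patient_id", how="inner", validate="one_to_one"
        )
    return frame_to_records(merged)


def complete_case_filter(
    records: Sequence[PatientRecord],
) -> Tuple[List[PatientRecord], List[Tuple[str, List[str]]]]:
    """Retain records with all 14 air-conduction thresholds present.

    Returns ``(retained, exclusion_log)`` where the log lists each dropped
    patient id with its missing fields.
    """
    retained, excluded = [], []
    for r in records:
        missing = [
            f"{side}_air_{f}"
            for side in ("left", "right")
            for f in AUDIOMETRIC_FREQS
            if r.air(side).get(f) is None
        ]
        if missing:
            excluded.append((r.patient_id, missing))
        else:
            retained.append(r)
    return retained, excluded


def write_labeled_csv(records: Sequence[PatientRecord],
                      labels: Sequence[SemanticLabels], path,
                      include_snomed: bool = True) -> pd.DataFrame:
    """One row per patient: raw columns, the four label columns, then the
    SNOMED concept-id columns.  Round-trips losslessly through
    :func:`read_labeled_csv`."""
    if len(records) != len(labels):
        raise ConfigurationError(
            f"length mismatch: {len(records)} records vs {len(labels)} labels"
        )
    df = records_to_frame(records)
    df[LABEL_COLUMNS["type"]] = [s.hl_type for s in labels]
    df[LABEL_COLUMNS["severity"]] = [s.severity for s in labels]
    df[LABEL_COLUMNS["laterality"]] = [s.laterality for s in labels]
    df[LABEL_COLUMNS["treatment"]] = [s.treatment for s in labels]
    df = df[list(RECORD_COLUMNS) + list(LABEL_COLUMN_ORDER)]
    if include_snomed:
        df = annotate_labels(df)
    df.to_csv(path, index=False)
    return df


def read_labeled_csv(path) -> Tuple[List[PatientRecord], pd.DataFrame]:
    """Inverse of :func:`write_labeled_csv`: records plus the label table."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    records = frame_to_records(df)
    label_cols = [c for c in list(LABEL_COLUMN_ORDER) + list(CONCEPT_COLUMNS.values())
                  if c in df.columns]
    return records, df[["patient_id"] + label_cols]


# ---------------------------------------------------------------------------
# RDF Turtle export
# ---------------------------------------------------------------------------

ONTO = Namespace("http://audiosem.example.org/onto#")

_CLASS_BY_DIMENSION = {
    "type": {"normal": "Hearing_Normal", "conductive": "Conductive_HL",
             "sensorineural": "Sensorineural_HL", "mixed": "Mixed_HL"},
    "severity": {"normal": "Severity_Normal", "mild": "Severity_Mild",
                 "moderate": "Severity_Moderate", "severe": "Severity_Severe",
                 "profound": "Severity_Profound"},
    "laterality": {"normal": "Laterality_Normal", "bilateral": "Bilateral",
                   "unilateral_left": "Unilateral_Left",
                   "unilateral_right": "Unilateral_Right"},
    "treatment": {"monitoring": "Treatment_Monitoring",
                  "hearing_aid": "Treatment_Hearing_Aid",
                  "cochlear_implant_evaluation": "Treatment_Cochlear_Implant_Evaluation",
                  "surgical_evaluation": "Treatment_Surgical_Evaluation",
                  "auditory_rehabilitation": "Treatment_Auditory_Rehabilitation"},
}

_SNOMED_PREDICATE = {dim: ONTO[f"has{dim.capitalize()}SnomedCode"]
                     for dim in _CLASS_BY_DIMENSION}


def export_turtle(records: Sequence[PatientRecord],
                  labels: Sequence[SemanticLabels], path,
                  mapping=None) -> Graph:
    """Serialize patients as named individuals with one class assertion per
    labeled dimension, data-property triples for their attributes and a
    SNOMED concept-id annotation where a mapped code exists."""
    from .snomed import to_snomed

    if len(records) != len(labels):
        raise ConfigurationError("records and labels length mismatch")
    g = Graph()
    g.bind("hl", ONTO)
    for record, sem in zip(records, labels):
        ind = ONTO[f"Patient_{record.patient_id}"]
        values = {"type": sem.hl_type, "severity": sem.severity,
                  "laterality": sem.laterality, "treatment": sem.treatment}
        for dim, value in values.items():
            if value is None:
                continue
            g.add((ind, RDF.type, ONTO[_CLASS_BY_DIMENSION[dim][value]]))
            concept = to_snomed(value, dimension=dim, mapping=mapping)
            if concept is not None:
                g.add((ind, _SNOMED_PREDICATE[dim],
                       Literal(concept.concept_id, datatype=XSD.string)))
        g.add((ind, ONTO.age, Literal(record.age, datatype=XSD.decimal)))
        for flag in COMORBIDITY_FLAGS:
            g.add((ind, ONTO[flag], Literal(bool(getattr(record, flag)))))
        for side in ("left", "right"):
            for f, v in sorted(record.air(side).items()):
                g.add((ind, ONTO[f"{side}_air_{f}"], Literal(v, datatype=XSD.decimal)))
            bone = record.bone(side)
            if bone:
                for f, v in sorted(bone.items()):
                    g.add((ind, ONTO[f"{side}_bone_{f}"], Literal(v, datatype=XSD.decimal)))
            tymp = record.tymp_abnormal(side)
            if tymp is not None:
                g.add((ind, ONTO[f"{side}_tymp_abnormal"], Literal(bool(tymp))))
    g.serialize(destination=str(path), format="turtle")
    return g
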