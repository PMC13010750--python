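"""SNOMED CT concept mapping for the internal label vocabularies.

The mapping ships as an editable tab-separated data file.  Only the three
hearing-loss-type codes with an established SNOMED CT correspondence are
asserted; every other vocabulary entry is carried as ``provisional`` with an
empty concept id, so unmapped concepts are retained in outputs (never
dropped) and can be filled in as terminology coverage evolves.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from .errors import ConfigurationError, SchemaError
from .vocab import DIMENSIONS, DIMENSION_VOCAB

#: label-table column carrying each dimension, as written by the CSV writer.
LABEL_COLUMNS = {
    "type": "Has_Type",
    "severity": "Has_Severity",
    "laterality": "Has_Laterality",
    "treatment": "recommendedTreatment",
}

#: concept-id columns appended by :func:`annotate_labels`.
CONCEPT_COLUMNS = {dim: f"snomed_{dim}" for dim in DIMENSIONS}


@dataclass(frozen=True)
class SnomedConcept:
    """One mapping entry; ``concept_id`` is None for unmapped concepts."""

    concept_id: Optional[str]
    preferred_term: str
    mapped_label: str
    dimension: str
    asserted: bool

    def __post_init__(self) -> None:
        if self.concept_id is not None and not self.concept_id.isdigit():
            raise ConfigurationError(
                f"SNOMED concept id must be digits, got {self.concept_id!r}"
            )


def _parse_mapping(text: str) -> Dict[tuple, SnomedConcept]:
    mapping: Dict[tuple, SnomedConcept] = {}
    reader = csv.reader(
        (line for line in io.StringIO(text) if line.strip() and not line.startswith("#")),
        delimiter="\t",
    )
    for row in reader:
        if len(row) != 4:
            raise ConfigurationError(f"mapping rows need 4 tab-separated fields, got {row}")
        qualified, concept_id, term, status = (c.strip() for c in row)
        dim, _, label = qualified.partition("/")
        if dim not in DIMENSIONS or label not in DIMENSION_VOCAB[dim]:
            raise ConfigurationError(f"unknown internal label {qualified!r} in mapping file")
        key = (dim, label)
        if key in mapping:
            raise ConfigurationError(f"duplicate mapping entry for {qualified!r}")
        mapping[key] = SnomedConcept(
            concept_id=concept_id or None,
            preferred_term=term,
            mapped_label=label,
            dimension=dim,
            asserted=(status == "asserted"),
        )
    return mapping


def load_mapping(path=None) -> Dict[tuple, SnomedConcept]:
    """Load the mapping table, from ``path`` or from the packaged default."""
    if path is None:
        text = resources.files("audiosem").joinpath("data/snomed_map.tsv").read_text("utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    return _parse_mapping(text)


_DEFAULT_MAPPING: Optional[Dict[tuple, SnomedConcept]] = None


def _default_mapping() -> Dict[tuple, SnomedConcept]:
    global _DEFAULT_MAPPING
    if _DEFAULT_MAPPING is None:
        _DEFAULT_MAPPING = load_mapping()
    return _DEFAULT_MAPPING


def to_snomed(label: str, dimension: str = "type",
              mapping: Optional[Dict[tuple, SnomedConcept]] = None) -> Optional[SnomedConcept]:
    """Resolve an internal label to its SNOMED CT concept, or None if unmapped.

    Raises :class:`ConfigurationError` for values outside the known
    vocabularies.
    """
    if dimension not in DIMENSIONS:
        raise ConfigurationError(f"unknown dimension {dimension!r}")
    if label not in DIMENSION_VOCAB[dimension]:
        raise ConfigurationError(f"unknown {dimension} label {label!r}")
    mapping = mapping if mapping is not None else _default_mapping()
    concept = mapping.get((dimension, label))
    if concept is None or concept.concept_id is None:
        return None
    return concept


def annotate_labels(table: pd.DataFrame,
                    mapping: Optional[Dict[tuple, SnomedConcept]] = None,
                    label_columns: Optional[Dict[str, str]] = None) -> pd.DataFrame:
    """Append one concept-id column per labeled dimension present in ``table``.

    Existing cells are never changed or reordered; unmapped labels yield empty
    concept cells; the row count is unchanged.  Raises :class:`SchemaError`
    when none of the expected label columns exist.
    """
    label_columns = label_columns or LABEL_COLUMNS
    present = {dim: col for dim, col in label_columns.items() if col in table.columns}
    if not present:
        raise SchemaError(
            f"table has none of the expected label columns {sorted(label_columns.values())}"
        )
    out = table.copy()
    for dim, col in present.items():
        def code(value, dim=dim):
            concept = to_snomed(str(value), dimension=dim, mapping=mapping)
            return concept.concept_id if concept is not None else ""
        out[CONCEPT_COLUMNS[dim]] = [code(v) for v in out[col]] if len(out) else pd.Series(dtype=object)
    return out
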