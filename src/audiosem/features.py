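"""Per-ear audiometric feature derivation.

This module turns raw pure-tone audiometry into the clinical quantities that
both labeling strategies and the classifier consume: pure-tone averages (PTA),
the air-bone gap (ABG), severity banding and the per-ear evidence predicates
for conductive and sensorineural pathology.

Evidence semantics
------------------
Conductive pathology is evidenced primarily by a sustained air-bone gap.  When
bone-conduction audiometry is unavailable (common in survey-style datasets),
an abnormal tympanogram together with elevated air thresholds serves as the
fallback indicator.  Sensorineural pathology is evidenced by elevated
bone-conduction thresholds; absent bone conduction, elevated air thresholds
with a *normal* (or missing) tympanogram default to sensorineural evidence,
the most prevalent adult etiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping, Optional, Sequence  # noqa: F401

from .errors import ConfigurationError, MissingDataError
from .vocab import (
    AUDIOMETRIC_FREQS,
    COMORBIDITY_FLAGS,
    DIMENSION_VOCAB,
    HF_FREQS,
    SEVERITIES,
)

THRESHOLD_MIN = -10.0
THRESHOLD_MAX = 120.0


@dataclass
class PatientRecord:
    """One subject: demographics, comorbidity flags and per-ear audiometry.

    Threshold maps are ``frequency (Hz) -> dB HL`` dictionaries over the seven
    standard frequencies.  Bone-conduction maps and tympanometry flags are
    optional, mirroring datasets where those modalities were not collected.
    """

    patient_id: str
    age: float
    sex: str
    ethnicity: str
    diabetes: bool
    hypertension: bool
    cardiovascular: bool
    noise_exposure: bool
    smoking: bool
    alcohol: bool
    left_air: dict = field(default_factory=dict)
    right_air: dict = field(default_factory=dict)
    left_bone: Optional[dict] = None
    right_bone: Optional[dict] = None
    left_tymp_abnormal: Optional[bool] = None
    right_tymp_abnormal: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in ("left_air", "right_air", "left_bone", "right_bone"):
            m = getattr(self, name)
            if m is None:
                continue
            for f, v in m.items():
                if f not in AUDIOMETRIC_FREQS:
                    raise ConfigurationError(
                        f"{self.patient_id}: unknown audiometric frequency {f} Hz in {name}"
                    )
                if v is not None and not (THRESHOLD_MIN <= v <= THRESHOLD_MAX):
                    raise ConfigurationError(
                        f"{self.patient_id}: threshold {v} dB HL at {f} Hz in {name} "
                        f"outside [{THRESHOLD_MIN}, {THRESHOLD_MAX}]"
                    )

    def air(self, side: str) -> dict:
        return self.left_air if side == "left" else self.right_air

    def bone(self, side: str) -> Optional[dict]:
        return self.left_bone if side == "left" else self.right_bone

    def tymp_abnormal(self, side: str) -> Optional[bool]:
        return self.left_tymp_abnormal if side == "left" else self.right_tymp_abnormal


@dataclass(frozen=True)
class EarFeatures:
    """Derived per-ear quantities consumed by the rule engine and clusterer."""

    pta: float
    hf_pta: float
    abg: Optional[float]
    has_loss: bool
    ear_severity: str
    conductive_evidence: bool
    sensorineural_evidence: bool


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable clinical cutoffs, with conventional audiological defaults.

    ``severity_cutoffs`` are the upper edges (dB HL, inclusive) of the
    normal / mild / moderate / severe bands; anything strictly above the last
    cutoff is profound.  The defaults (25/40/70/90) place the profound
    boundary at a pure-tone average strictly exceeding 90 dB HL.
    """

    pta_freqs: Sequence[int] = (500, 1000, 2000, 4000)
    hl_cutoff: float = 25.0
    abg_threshold: float = 15.0
    bone_normal_max: float = 25.0
    severity_cutoffs: Sequence[float] = (25.0, 40.0, 70.0, 90.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pta_freqs", tuple(self.pta_freqs))
        object.__setattr__(self, "severity_cutoffs", tuple(float(c) for c in self.severity_cutoffs))
        if not self.pta_freqs:
            raise ConfigurationError("pta_freqs must not be empty")
        unknown = [f for f in self.pta_freqs if f not in AUDIOMETRIC_FREQS]
        if unknown:
            raise ConfigurationError(f"pta_freqs contains unsupported frequencies: {unknown}")
        if len(self.severity_cutoffs) != len(SEVERITIES) - 1:
            raise ConfigurationError(
                f"severity_cutoffs needs {len(SEVERITIES) - 1} values, got {len(self.severity_cutoffs)}"
            )
        if any(b <= a for a, b in zip(self.severity_cutoffs, self.severity_cutoffs[1:])):
            raise ConfigurationError("severity_cutoffs must be strictly increasing")

    def severity_band(self, pta: float) -> str:
        """Band of a pure-tone average; total and monotone on the real line."""
        for name, cutoff in zip(SEVERITIES, self.severity_cutoffs):
            if pta <= cutoff:
                return name
        return SEVERITIES[-1]

    # -- plain-text serialization (key = value, units documented in header) --

    def to_file(self, path) -> None:
        lines = [
            "# audiosem feature configuration",
            "# frequencies in Hz, levels in dB HL",
            "pta_freqs = " + ",".join(str(f) for f in self.pta_freqs),
            f"hl_cutoff = {self.hl_cutoff:g}",
            f"abg_threshold = {self.abg_threshold:g}",
            f"bone_normal_max = {self.bone_normal_max:g}",
            "severity_cutoffs = " + ",".join(f"{c:g}" for c in self.severity_cutoffs),
        ]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path) -> "FeatureConfig":
        values = {}
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"unparseable config line: {raw!r}")
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
        known = {f.name for f in dc_fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        if "pta_freqs" in values:
            kwargs["pta_freqs"] = tuple(int(x) for x in values["pta_freqs"].split(","))
        if "severity_cutoffs" in values:
            kwargs["severity_cutoffs"] = tuple(float(x) for x in values["severity_cutoffs"].split(","))
        for key in ("hl_cutoff", "abg_threshold", "bone_normal_max"):
            if key in values:
                kwargs[key] = float(values[key])
        return cls(**kwargs)


def pure_tone_average(thresholds: Mapping[int, float], freqs: Sequence[int]) -> float:
    """Arithmetic mean of the thresholds at ``freqs`` (dB HL)."""
    total = 0.0
    for f in freqs:
        v = thresholds.get(f)
        if v is None:
            raise MissingDataError(f"missing threshold at {f} Hz")
        total += v
    return total / len(freqs)


def air_bone_gap(air: Mapping[int, float], bone: Mapping[int, float], freqs: Sequence[int]) -> float:
    """Mean per-frequency air-minus-bone difference, clamped at 0 per frequency.

    Negative per-frequency gaps are treated as measurement noise.
    """
    total = 0.0
    for f in freqs:
        a, b = air.get(f), bone.get(f)
        if a is None or b is None:
            raise MissingDataError(f"missing threshold at {f} Hz")
        total += max(a - b, 0.0)
    return total / len(freqs)


def _bone_usable(bone: Optional[Mapping[int, float]], freqs: Sequence[int]) -> bool:
    return bone is not None and all(bone.get(f) is not None for f in freqs)


def ear_profile(record: PatientRecord, side: str, config: FeatureConfig) -> EarFeatures:
    """Derive all :class:`EarFeatures` for one ear of a record.

    Pure function of its inputs.  Raises :class:`MissingDataError` when the
    air-conduction map is incomplete for the configured PTA frequencies.
    """
    if side not in ("left", "right"):
        raise ConfigurationError(f"side must be 'left' or 'right', got {side!r}")
    air = record.air(side)
    pta = pure_tone_average(air, config.pta_freqs)
    hf = pure_tone_average(air, [f for f in HF_FREQS if f in air] or HF_FREQS)
    has_loss = pta > config.hl_cutoff

    bone = record.bone(side)
    tymp = record.tymp_abnormal(side)
    if _bone_usable(bone, config.pta_freqs):
        abg = air_bone_gap(air, bone, config.pta_freqs)
        bone_pta = pure_tone_average(bone, config.pta_freqs)
        conductive = abg >= config.abg_threshold
        sensorineural = bone_pta > config.bone_normal_max
    else:
        abg = None
        conductive = bool(tymp) and has_loss
        # With no bone conduction, a hearing loss that is not attributed to a
        # middle-ear problem (abnormal tympanogram) defaults to sensorineural.
        sensorineural = (tymp is None or tymp is False) and has_loss

    return EarFeatures(
        pta=pta,
        hf_pta=hf,
        abg=abg,
        has_loss=has_loss,
        ear_severity=config.severity_band(pta),
        conductive_evidence=conductive,
        sensorineural_evidence=sensorineural,
    )


# ---------------------------------------------------------------------------
# classifier feature vectors
# ---------------------------------------------------------------------------

_SEMANTIC_ATTR = {
    "type": "hl_type",
    "severity": "severity",
    "laterality": "laterality",
    "treatment": "treatment",
}


def _raw_columns(include_tymp: bool) -> list:
    cols = ["age"] + list(COMORBIDITY_FLAGS)
    cols += [f"left_air_{f}" for f in AUDIOMETRIC_FREQS]
    cols += [f"right_air_{f}" for f in AUDIOMETRIC_FREQS]
    if include_tymp:
        cols += ["left_tymp_abnormal", "right_tymp_abnormal"]
    return cols


def feature_vector(
    record: PatientRecord,
    config: FeatureConfig,
    include_semantic=None,
    semantic_fields: Sequence[str] = ("severity", "laterality"),
):
    """Ordered ``column -> numeric value`` mapping for one record.

    Raw columns are age, the six comorbidity flags, the 14 air-conduction
    thresholds and (when measured) the two tympanometry flags.  When
    ``include_semantic`` labels are supplied, the requested semantic
    dimensions are appended as categorical codes; the target dimension of a
    learning task must not be among them (anti-leakage contract enforced by
    the pipeline).
    """
    out = {"age": float(record.age)}
    for flag in COMORBIDITY_FLAGS:
        out[flag] = float(bool(getattr(record, flag)))
    for side in ("left", "right"):
        air = record.air(side)
        for f in AUDIOMETRIC_FREQS:
            v = air.get(f)
            if v is None:
                raise MissingDataError(
                    f"{record.patient_id}: missing {side} air threshold at {f} Hz"
                )
            out[f"{side}_air_{f}"] = float(v)
    if record.left_tymp_abnormal is not None and record.right_tymp_abnormal is not None:
        out["left_tymp_abnormal"] = float(record.left_tymp_abnormal)
        out["right_tymp_abnormal"] = float(record.right_tymp_abnormal)
    if include_semantic is not None:
        for dim in semantic_fields:
            vocab = DIMENSION_VOCAB[dim]
            value = getattr(include_semantic, _SEMANTIC_ATTR[dim])
            out[f"sem_{dim}"] = float(vocab.index(value))
    return out


def feature_frame(
    records: Sequence[PatientRecord],
    config: FeatureConfig,
    semantic=None,
    semantic_fields: Sequence[str] = ("severity", "laterality"),
):
    """Stack :func:`feature_vector` rows into a DataFrame with stable columns."""
    import pandas as pd

    if semantic is not None and len(semantic) != len(records):
        raise ConfigurationError("semantic labels and records length mismatch")
    rows = [
        feature_vector(
            r,
            config,
            include_semantic=None if semantic is None else semantic[i],
            semantic_fields=semantic_fields,
        )
        for i, r in enumerate(records)
    ]
    df = pd.DataFrame(rows)
    # tympanometry columns are kept only when measured for every record
    if df[["left_air_500"]].isna().any().any():  # pragma: no cover - defensive
        raise MissingDataError("incomplete audiometry slipped past feature_vector")
    if "left_tymp_abnormal" in df.columns and df["left_tymp_abnormal"].isna().any():
        df = df.drop(columns=["left_tymp_abnormal", "right_tymp_abnormal"])
    return df
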