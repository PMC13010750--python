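"""Synthetic audiometric cohort generation with known generative labels.

The generator emulates a survey-style adult audiometry table: air-conduction
thresholds at the seven standard frequencies for both ears, optional
bone-conduction thresholds, a binary tympanometry-quality flag per ear,
demographics, comorbidity flags and lifestyle factors -- with the generative
hearing-loss type / severity / laterality recorded separately so every
downstream stage can be scored against ground truth.

Audiogram shapes by type
------------------------
* normal: all thresholds at 0-15 dB HL, bone equal to air.
* sensorineural: sloping high-frequency loss (thresholds rise linearly above
  2000 Hz), bone tracking air (no air-bone gap).
* conductive: flat elevated air curve over normal bone (air-bone gap >= 20 dB).
* mixed: the sensorineural slope plus a constant 20 dB air-bone gap over
  elevated bone.

Noise-free audiograms are constructed on the 5 dB audiometer grid strictly
inside the target severity band (>= 2 dB from each boundary), so generative
labels are unambiguous at ``noise_sd = 0``.  Measurement noise is then added
per threshold and the result re-quantized to the configured step and clipped
to the instrument range [-10, 120] dB HL.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError
from .features import PatientRecord
from .vocab import (
    AUDIOMETRIC_FREQS,
    COMORBIDITY_FLAGS,
    ETHNICITIES,
    HL_TYPES,
    LATERALITIES,
    SEVERITIES,
    SEXES,
)

#: Noise-free flat/base levels (dB HL) available per severity band; all are on
#: the 5 dB grid and keep the resulting four-frequency PTA >= 2 dB inside the
#: band (normal <= 25 < mild <= 40 < moderate <= 70 < severe <= 90 < profound).
SEVERITY_LEVEL_POOL: Dict[str, Tuple[float, ...]] = {
    "mild": (30.0, 35.0),
    "moderate": (45.0, 50.0, 55.0, 60.0, 65.0),
    "severe": (75.0, 80.0, 85.0),
    "profound": (95.0, 100.0, 105.0),
}

#: A mixed ear needs bone PTA > 25 plus a 20 dB air-bone gap, which forces the
#: air PTA to at least ~50 dB HL; mild mixed loss is therefore infeasible and
#: the moderate pool starts at 50.
MIXED_LEVEL_POOL: Dict[str, Tuple[float, ...]] = {
    "moderate": (50.0, 55.0, 60.0, 65.0),
    "severe": (75.0, 80.0, 85.0),
    "profound": (95.0, 100.0, 105.0),
}
MIXED_SEVERITIES = tuple(MIXED_LEVEL_POOL)
MIXED_ABG = 20.0

#: High-frequency slope offsets (dB) added above 2000 Hz for sensorineural and
#: mixed ears; chosen so the 0.5/1/2/4 kHz PTA equals base + 5 dB.
SLOPE_OFFSETS = {500: 0.0, 1000: 0.0, 2000: 0.0, 3000: 10.0,
                 4000: 20.0, 6000: 25.0, 8000: 30.0}

NORMAL_LEVELS = (0.0, 5.0, 10.0, 15.0)
CONDUCTIVE_BONE_LEVELS = (5.0, 10.0)

#: Probability that the tympanogram flag reads abnormal, by whether the ear
#: carries a conductive component (conductive / mixed) or not.
TYMP_ABNORMAL_P = {"conductive_component": 0.95, "other": 0.05}

_DEFAULT_TYPE_MIX = {"normal": 0.45, "conductive": 0.15,
                     "sensorineural": 0.30, "mixed": 0.10}
_DEFAULT_SEVERITY_MIX = {"mild": 0.45, "moderate": 0.35,
                         "severe": 0.12, "profound": 0.08}
_DEFAULT_LATERALITY_MIX = {"bilateral": 0.60, "unilateral_left": 0.20,
                           "unilateral_right": 0.20}
_DEFAULT_COMORBIDITY = {"diabetes": 0.13, "hypertension": 0.33,
                        "cardiovascular": 0.08, "noise_exposure": 0.25,
                        "smoking": 0.20, "alcohol": 0.55}


def _check_proportions(name: str, mix: Mapping[str, float], keys: Sequence[str]) -> None:
    if set(mix) != set(keys):
        raise ConfigurationError(f"{name} must have keys {sorted(keys)}, got {sorted(mix)}")
    if any(v < 0 for v in mix.values()):
        raise ConfigurationError(f"{name} has negative proportions")
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} proportions must sum to 1 (got {sum(mix.values())})")


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for one synthetic cohort."""

    n_patients: int
    seed: int = 0
    type_mix: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_TYPE_MIX))
    severity_mix: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_SEVERITY_MIX))
    laterality_mix: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_LATERALITY_MIX))
    noise_sd: float = 5.0
    quantization_step: float = 5.0
    comorbidity_prevalences: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_COMORBIDITY))
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be non-negative")
        _check_proportions("type_mix", self.type_mix, HL_TYPES)
        _check_proportions("severity_mix", self.severity_mix, SEVERITIES[1:])
        _check_proportions("laterality_mix", self.laterality_mix, LATERALITIES[1:])
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.quantization_step <= 0:
            raise ConfigurationError("quantization_step must be > 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1]")
        if set(self.comorbidity_prevalences) != set(COMORBIDITY_FLAGS):
            raise ConfigurationError(
                f"comorbidity_prevalences must cover {COMORBIDITY_FLAGS}"
            )


@dataclass(frozen=True)
class GenerativeTruth:
    """Per-patient labels sampled before noise was applied."""

    patient_id: str
    hl_type: str
    severity: str
    laterality: str


def _flat(level: float) -> dict:
    return {f: level for f in AUDIOMETRIC_FREQS}


def _sloped(base: float) -> dict:
    return {f: min(base + SLOPE_OFFSETS[f], 120.0) for f in AUDIOMETRIC_FREQS}


def _normal_ear(rng: np.random.Generator) -> Tuple[dict, dict]:
    air = {f: float(rng.choice(NORMAL_LEVELS)) for f in AUDIOMETRIC_FREQS}
    return air, dict(air)


def _affected_ear(true_type: str, severity: str, rng: np.random.Generator) -> Tuple[dict, dict]:
    if true_type == "sensorineural":
        level = float(rng.choice(SEVERITY_LEVEL_POOL[severity]))
        air = _sloped(level - 5.0)
        return air, dict(air)
    if true_type == "conductive":
        level = float(rng.choice(SEVERITY_LEVEL_POOL[severity]))
        bone_level = float(rng.choice(CONDUCTIVE_BONE_LEVELS))
        return _flat(level), _flat(bone_level)
    if true_type == "mixed":
        level = float(rng.choice(MIXED_LEVEL_POOL[severity]))
        air = _sloped(level - 5.0)
        bone = {f: air[f] - MIXED_ABG for f in AUDIOMETRIC_FREQS}
        return air, bone
    raise ConfigurationError(f"unknown affected-ear type {true_type!r}")


def sample_audiogram(true_type: str, true_severity: Optional[str],
                     affected: Sequence[str],
                     rng: Optional[np.random.Generator] = None,
                     seed: int = 0) -> Dict[str, Tuple[dict, dict]]:
    """Noise-free per-ear ``(air, bone)`` threshold maps for one patient.

    ``affected`` is the set of affected ears (subset of {'left', 'right'},
    empty for normal hearing).  Affected ears realize the type's shape inside
    the severity band; unaffected ears are normal.
    """
    if true_type not in HL_TYPES:
        raise ConfigurationError(f"unknown type {true_type!r}")
    if true_type != "normal":
        pool = MIXED_LEVEL_POOL if true_type == "mixed" else SEVERITY_LEVEL_POOL
        if true_severity not in pool:
            raise ConfigurationError(
                f"severity {true_severity!r} not generatable for type {true_type!r}"
            )
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = {}
    for side in ("left", "right"):
        if side in affected and true_type != "normal":
            out[side] = _affected_ear(true_type, true_severity, rng)
        else:
            out[side] = _normal_ear(rng)
    return out


def _quantize_clip(value: float, step: float) -> float:
    q = step * round(value / step)
    return float(min(max(q, -10.0), 120.0))


def _renormalize(mix: Mapping[str, float], keys: Sequence[str]) -> Tuple[List[str], List[float]]:
    probs = [mix[k] for k in keys]
    total = sum(probs)
    if total <= 0:
        raise ConfigurationError(
            f"severity_mix assigns zero mass to the feasible bands {list(keys)}"
        )
    return list(keys), [p / total for p in probs]


_AFFECTED = {"bilateral": ("left", "right"),
             "unilateral_left": ("left",),
             "unilateral_right": ("right",)}


def generate_cohort(config: CohortConfig) -> Tuple[List[PatientRecord], List[GenerativeTruth]]:
    """Generate ``config.n_patients`` records plus their generative truth.

    Deterministic: identical config (including seed) reproduces the cohort
    exactly.  When ``config.missing_rate`` > 0 the returned records have
    audiometric cells blanked via :func:`inject_missingness` (seeded from the
    cohort seed).
    """
    rng = np.random.default_rng(config.seed)
    type_keys = list(HL_TYPES)
    type_p = [config.type_mix[k] for k in type_keys]
    lat_keys = list(LATERALITIES[1:])
    lat_p = [config.laterality_mix[k] for k in lat_keys]
    sev_keys, sev_p = _renormalize(config.severity_mix, SEVERITIES[1:])
    mixed_sev_keys, mixed_sev_p = None, None
    if config.type_mix["mixed"] > 0:
        mixed_sev_keys, mixed_sev_p = _renormalize(config.severity_mix, MIXED_SEVERITIES)

    records, truths = [], []
    for i in range(config.n_patients):
        pid = f"SYN{i:05d}"
        age = float(rng.integers(20, 81))
        sex = str(rng.choice(SEXES))
        ethnicity = str(rng.choice(ETHNICITIES))
        flags = {flag: bool(rng.random() < config.comorbidity_prevalences[flag])
                 for flag in COMORBIDITY_FLAGS}

        hl_type = str(rng.choice(type_keys, p=type_p))
        if hl_type == "normal":
            severity, laterality, affected = "normal", "normal", ()
        else:
            laterality = str(rng.choice(lat_keys, p=lat_p))
            if hl_type == "mixed":
                severity = str(rng.choice(mixed_sev_keys, p=mixed_sev_p))
            else:
                severity = str(rng.choice(sev_keys, p=sev_p))
            affected = _AFFECTED[laterality]

        audio = sample_audiogram(hl_type, None if hl_type == "normal" else severity,
                                 affected, rng=rng)
        maps = {}
        for side in ("left", "right"):
            air, bone = audio[side]
            for m, name in ((air, f"{side}_air"), (bone, f"{side}_bone")):
                noisy = {}
                for f in AUDIOMETRIC_FREQS:
                    v = m[f]
                    if config.noise_sd > 0:
                        v += float(rng.normal(0.0, config.noise_sd))
                    noisy[f] = _quantize_clip(v, config.quantization_step)
                maps[name] = noisy

        tymp = {}
        for side in ("left", "right"):
            has_conductive = side in affected and hl_type in ("conductive", "mixed")
            p = TYMP_ABNORMAL_P["conductive_component" if has_conductive else "other"]
            tymp[side] = bool(rng.random() < p)

        records.append(PatientRecord(
            patient_id=pid, age=age, sex=sex, ethnicity=ethnicity,
            **flags,
            left_air=maps["left_air"], right_air=maps["right_air"],
            left_bone=maps["left_bone"], right_bone=maps["right_bone"],
            left_tymp_abnormal=tymp["left"], right_tymp_abnormal=tymp["right"],
        ))
        truths.append(GenerativeTruth(patient_id=pid, hl_type=hl_type,
                                      severity=severity, laterality=laterality))

    if config.missing_rate > 0:
        records = inject_missingness(records, config.missing_rate, config.seed)
    return records, truths


def inject_missingness(records: Sequence[PatientRecord], rate: float,
                       seed: int) -> List[PatientRecord]:
    """Blank each audiometric cell independently with probability ``rate``.

    Demographics and labels are never touched.  Returns deep copies;
    deterministic per seed.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError("missingness rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for record in records:
        r = copy.deepcopy(record)
        for name in ("left_air", "right_air", "left_bone", "right_bone"):
            m = getattr(r, name)
            if m is None:
                continue
            for f in AUDIOMETRIC_FREQS:
                if f in m and rng.random() < rate:
                    del m[f]
        out.append(r)
    return out
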