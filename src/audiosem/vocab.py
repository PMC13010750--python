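"""Shared label vocabularies and audiometric constants.

All label values are lowercase snake-case strings so they survive CSV
round-trips and can be compared verbatim inside rule conditions.
"""

#: The seven air-conduction test frequencies (Hz) carried by every record.
AUDIOMETRIC_FREQS = (500, 1000, 2000, 3000, 4000, 6000, 8000)

#: High-frequency subset used for the high-frequency pure-tone average.
HF_FREQS = (3000, 4000, 6000)

HL_TYPES = ("normal", "conductive", "sensorineural", "mixed")
SEVERITIES = ("normal", "mild", "moderate", "severe", "profound")
LATERALITIES = ("normal", "bilateral", "unilateral_left", "unilateral_right")
TREATMENTS = (
    "monitoring",
    "hearing_aid",
    "cochlear_implant_evaluation",
    "surgical_evaluation",
    "auditory_rehabilitation",
)

#: Inference dimensions in the order the rule engine resolves them.
DIMENSIONS = ("type", "severity", "laterality", "treatment")

DIMENSION_VOCAB = {
    "type": HL_TYPES,
    "severity": SEVERITIES,
    "laterality": LATERALITIES,
    "treatment": TREATMENTS,
}

COMORBIDITY_FLAGS = (
    "diabetes",
    "hypertension",
    "cardiovascular",
    "noise_exposure",
    "smoking",
    "alcohol",
)

SEXES = ("female", "male")
ETHNICITIES = (
    "mexican_american",
    "other_hispanic",
    "non_hispanic_white",
    "non_hispanic_black",
    "other",
)
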