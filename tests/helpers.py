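"""Shared test construction helpers."""

from audiosem.features import PatientRecord
from audiosem.vocab import AUDIOMETRIC_FREQS


def make_record(air_level=10.0, bone_level=None, tymp=None, air=None, bone=None, **kw):
    """A single-patient record with flat audiograms, overridable per field."""
    air = air if air is not None else {f: air_level for f in AUDIOMETRIC_FREQS}
    if bone is None and bone_level is not None:
        bone = {f: bone_level for f in AUDIOMETRIC_FREQS}
    defaults = dict(
        patient_id="P1", age=50.0, sex="female", ethnicity="other",
        diabetes=False, hypertension=False, cardiovascular=False,
        noise_exposure=False, smoking=False, alcohol=False,
        left_air=air, right_air=dict(air),
        left_bone=bone, right_bone=None if bone is None else dict(bone),
        left_tymp_abnormal=tymp, right_tymp_abnormal=tymp,
    )
    defaults.update(kw)
    return PatientRecord(**defaults)
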