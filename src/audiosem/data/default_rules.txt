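# audiosem rule base
version = 1

[rule type_mixed]
dimension = type
priority = 10
when = conductive_any and sensorineural_any
assert = mixed
description = Both conductive and sensorineural characteristics detected in the same patient.

[rule type_conductive]
dimension = type
priority = 20
when = conductive_any and not sensorineural_any
assert = conductive
description = Conductive evidence (air-bone gap or abnormal tympanogram with loss) only.

[rule type_sensorineural]
dimension = type
priority = 30
when = not conductive_any and (sensorineural_any or loss_any)
assert = sensorineural
description = Sensorineural evidence, or hearing loss without specific evidence (default adult etiology).

[rule type_normal]
dimension = type
priority = 40
when = not conductive_any and not sensorineural_any and not loss_any
assert = normal
description = No hearing loss and no pathological evidence in either ear.

[rule severity_normal]
dimension = severity
priority = 10
when = worse_pta <= 25
assert = normal
description = Worse-ear PTA within normal limits.

[rule severity_mild]
dimension = severity
priority = 20
when = worse_pta > 25 and worse_pta <= 40
assert = mild
description = Mild band.

[rule severity_moderate]
dimension = severity
priority = 30
when = worse_pta > 40 and worse_pta <= 70
assert = moderate
description = Moderate band.

[rule severity_severe]
dimension = severity
priority = 40
when = worse_pta > 70 and worse_pta <= 90
assert = severe
description = Severe band.

[rule severity_profound]
dimension = severity
priority = 50
when = worse_pta > 90
assert = profound
description = Profound hearing loss when the pure-tone average exceeds 90 dB HL.

[rule laterality_bilateral]
dimension = laterality
priority = 10
when = left_has_loss and right_has_loss
assert = bilateral
description = Both ears demonstrate hearing loss.

[rule laterality_left]
dimension = laterality
priority = 20
when = left_has_loss and not right_has_loss
assert = unilateral_left
description = Left ear only.

[rule laterality_right]
dimension = laterality
priority = 30
when = right_has_loss and not left_has_loss
assert = unilateral_right
description = Right ear only.

[rule laterality_normal]
dimension = laterality
priority = 40
when = not left_has_loss and not right_has_loss
assert = normal
description = Neither ear shows loss.

[rule treat_cochlear_implant]
dimension = treatment
priority = 10
when = hl_type == 'sensorineural' and severity in {'severe', 'profound'} and laterality == 'bilateral'
assert = cochlear_implant_evaluation
description = Cochlear implant candidacy for bilateral severe-to-profound sensorineural loss; the limited-hearing-aid-benefit clause is not measurable in these data.

[rule treat_surgical]
dimension = treatment
priority = 20
when = hl_type in {'conductive', 'mixed'} and severity != 'normal'
assert = surgical_evaluation
description = Conductive or mixed loss warrants surgical / otological evaluation.

[rule treat_hearing_aid]
dimension = treatment
priority = 30
when = hl_type == 'sensorineural' and severity != 'normal' and not (severity in {'severe', 'profound'} and laterality == 'bilateral')
assert = hearing_aid
description = Mild-to-moderate, or unilateral severe-to-profound, sensorineural loss.

[rule treat_monitoring_normal]
dimension = treatment
priority = 40
when = hl_type == 'normal'
assert = monitoring
description = Normal hearing: periodic monitoring.

[rule treat_monitoring_default]
dimension = treatment
priority = 50
when = true
assert = monitoring
description = Fallback for subclinical evidence without measurable loss.
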