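# internal_label	concept_id	preferred_term	status
# Only hearing-loss-type codes with an established SNOMED CT correspondence
# are asserted; other entries are provisional placeholders retained for
# completeness (empty concept_id = deliberately unmapped).
type/sensorineural	60700002	Sensorineural hearing loss	asserted
type/conductive	44057008	Conductive hearing loss	asserted
type/mixed	36885005	Mixed conductive and sensorineural hearing loss	asserted
type/normal		Normal hearing	provisional
severity/normal		Hearing within normal limits	provisional
severity/mild		Mild hearing loss	provisional
severity/moderate		Moderate hearing loss	provisional
severity/severe		Severe hearing loss	provisional
severity/profound		Profound hearing loss	provisional
laterality/normal		No lateralized hearing loss	provisional
laterality/bilateral		Bilateral hearing loss	provisional
laterality/unilateral_left		Unilateral hearing loss, left	provisional
laterality/unilateral_right		Unilateral hearing loss, right	provisional
treatment/monitoring		Audiological monitoring	provisional
treatment/hearing_aid		Hearing aid provision	provisional
treatment/cochlear_implant_evaluation		Cochlear implant candidacy evaluation	provisional
treatment/surgical_evaluation		Otological surgical evaluation	provisional
treatment/auditory_rehabilitation		Auditory rehabilitation	provisional
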