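point_id,field,original_value,corrected_value,action,rationale
Atkins,course,9.5x2,12x2,modify,Monte-Carlo recalculation of the 22.5 MeV electron beam puts the maximum cord dose at prescription level (12 Gy x 2) rather than the recorded 9.5 Gy x 2
Eichhorn,total,142,46,modify,incidence denominator misquoted as 142 in later compilations; the original report gives 8/46
Abbatucci,included,True,False,exclude,cord dose of the 94-patient 3 Gy x 18 control group cannot be verified from the original report
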