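study,species,site,events,total,course,included,note
Powers,dog,thoracic,3,12,4x11,True,
Powers,dog,thoracic,6,12,4x13,True,
Powers,dog,thoracic,17,17,4x17,True,
Powers,dog,thoracic,2,12,2x30,True,
Powers,dog,thoracic,1,6,2x34,True,
Powers,dog,thoracic,3,6,2x38,True,
Powers,dog,thoracic,5,6,2x42,True,
Schultheiss,monkey,mixed,3,15,2.2x32,True,C1-T2 field
Schultheiss,monkey,mixed,3,6,2.2x35,True,C1-T2 field
Schultheiss,monkey,mixed,7,8,2.2x38,True,C1-T2 field
Schultheiss,monkey,mixed,6,16,2.2x32,True,C1-T2 field; second cohort at same regimen kept as printed
Medin,pig,cervical,0,5,16x1,True,C4-7 field
Medin,pig,cervical,1,5,18x1,True,C4-7 field
Medin,pig,cervical,4,5,20x1,True,C4-7 field
Medin,pig,cervical,4,4,22x1,True,C4-7 field
Medin,pig,cervical,4,4,24x1,True,C4-7 field
Reinhold,human,thoracic,0,2,2.1x22,True,source table lists site C; narrative reports thoracic myelopathy
Reinhold,human,thoracic,1,5,2.1x26,True,source table lists site C; narrative reports thoracic myelopathy
Reinhold,human,thoracic,2,4,2.2x28,True,source table lists site C; narrative reports thoracic myelopathy
Reinhold,human,thoracic,5,9,2.2x30,True,source table lists site C; narrative reports thoracic myelopathy
Reinhold,human,thoracic,0,2,2.5x20,True,source table lists site C; narrative reports thoracic myelopathy
Reinhold,human,thoracic,2,4,2.5x25,True,source table lists site C; narrative reports thoracic myelopathy
Reinhold,human,thoracic,4,6,2.5x28,True,source table lists site C; narrative reports thoracic myelopathy
Reinhold,human,thoracic,4,9,3x21,True,source table lists site C; narrative reports thoracic myelopathy
Reinhold,human,thoracic,2,2,3.5x18,True,source table lists site C; narrative reports thoracic myelopathy
McCunniff,human,cervical,1,12,2x30,True,
Jeremic; McCunniff,human,cervical,0,43,1.63x40,True,pooled 0/24 + 0/19 at identical regimen
Abbatucci,human,cervical,7,15,3x18,True,
Atkins,human,cervical,4,13,9.5x2,True,recorded cord dose 9.5 Gy x 2
Marcus,human,cervical,0,211,1.9x25,True,
Marcus,human,cervical,0,22,1.9x28,True,
Marcus,human,cervical,2,19,2x30,True,
Hazra; Choi,human,thoracic,1,91,3x15,True,pooled 1/16 + 0/75
Abramson; Fitzgerald; Madden; Guthrie,human,thoracic,11,401,4x10,True,pooled 4/271 + 6/45 + 1/43 + 0/42
Dische,human,thoracic,13,145,5.7x6,True,
Haltlevoll,human,thoracic,8,157,6x3+4x5,True,
Haltlevoll,human,thoracic,9,230,6x3+4x3+2x2,True,
Eichhorn,human,thoracic,8,142,2.45x27,True,denominator as misquoted in later compilations
Scruggs,human,thoracic,2,248,4x5+2.5x8,True,
Macbeth,human,thoracic,3,524,9.2x2,True,
Macbeth,human,thoracic,2,153,3.1x13,True,
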