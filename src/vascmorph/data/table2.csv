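# Branching statistics of the pulmonary arterial (PA) and venous (PV) trees
# of Monodelphis domestica at four postnatal stages, per lung side and for the
# whole lung. median_generation and maximum_generation count branch
# generations with the main trunk as generation 0; vessel_count is the number
# of centerline segments. Stage presets of the phantom generator are
# constrained to the scope=total rows.
stage,vessel,scope,median_generation,maximum_generation,vessel_count
neonate,PA,right,7,10,24
neonate,PA,left,4,6,10
neonate,PA,total,5,10,41
neonate,PV,right,4.5,8,18
neonate,PV,left,4,6,7
neonate,PV,total,4,6,17
21dpn,PA,right,6,10,34
21dpn,PA,left,6,9,29
21dpn,PA,total,6,10,56
21dpn,PV,right,6,9,24
21dpn,PV,left,7,12,41
21dpn,PV,total,6,12,70
35dpn,PA,right,10,20,141
35dpn,PA,left,7,11,70
35dpn,PA,total,10,20,202
35dpn,PV,right,9,16,61
35dpn,PV,left,8,14,48
35dpn,PV,total,8,14,118
57dpn,PA,right,16,27,404
57dpn,PA,left,12,25,358
57dpn,PA,total,14,27,695
57dpn,PV,right,12,24,292
57dpn,PV,left,11,25,286
57dpn,PV,total,12,25,644
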