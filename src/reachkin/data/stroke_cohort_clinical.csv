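id,gender,age,latency_months,stroke_type,affected_side,barthel,fma
CR,male,76,3,hemorrhagic,right,52,46
LG,male,83,6,ischemic,left,57,38
SF,female,80,2,ischemic,right,58,42
SFl,female,64,1,ischemic,right,56,53
CE,female,81,3,hemorrhagic,left,34,48
SA,male,84,5,ischemic,right,41,34
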