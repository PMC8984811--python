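name,older,younger,ordinal
MN1,23.0,21.7,1
MN2,21.7,19.5,2
MN3,19.5,17.2,3
MN4,17.2,16.4,4
MN5,16.4,14.2,5
MN6,14.2,12.85,6
MN7-8,12.85,11.2,7
MN9,11.2,9.9,8
MN10,9.9,8.9,9
MN11,8.9,7.6,10
MN12,7.6,7.1,11
MN13,7.1,5.3,12
MN14,5.3,5.0,13
MN15,5.0,3.55,14
MN16,3.55,2.5,15
MN17,2.5,1.9,16
MQ18,1.9,0.85,17
MQ19,0.85,0.01,18
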