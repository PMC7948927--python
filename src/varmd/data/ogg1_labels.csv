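variant,label
WT,unaffected
E92D,unaffected
H111R,unaffected
S118F,unaffected
I145M,affected
R161W,ambiguous
G202C,affected
R206C,unaffected
Q226H,unaffected
Q263H,unaffected
V267M,affected
T285M,unaffected
P291Q,unaffected
S292N,ambiguous
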