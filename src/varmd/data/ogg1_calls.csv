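variant,SIFT,FATHMM,MutationTaster,PROVEAN
R87K,unaffected,unaffected,unaffected,unaffected
P88L,unaffected,unaffected,affected,unaffected
E92D,unaffected,unaffected,affected,unaffected
R97C,affected,unaffected,unaffected,affected
H111R,unaffected,unaffected,unaffected,unaffected
S115F,affected,unaffected,unaffected,affected
S118F,affected,unaffected,affected,affected
R131G,affected,affected,affected,affected
I145M,affected,unaffected,affected,affected
A153T,unaffected,affected,unaffected,unaffected
R161W,affected,affected,affected,affected
G202C,affected,affected,affected,affected
R206C,affected,affected,affected,affected
Q226H,unaffected,unaffected,affected,unaffected
R229Q,unaffected,unaffected,unaffected,affected
Q263H,affected,unaffected,affected,unaffected
V267M,affected,unaffected,affected,affected
T285M,unaffected,unaffected,unaffected,unaffected
P291Q,affected,unaffected,unaffected,unaffected
S292N,unaffected,unaffected,unaffected,unaffected
WT,unaffected,unaffected,unaffected,unaffected
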