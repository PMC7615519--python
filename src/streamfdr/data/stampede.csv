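id,pval,batch
B,0.450,1
C,0.006,1
E,0.022,1
D,0.847,2
F,0.130,2
G,0.001,3
H,0.266,4
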