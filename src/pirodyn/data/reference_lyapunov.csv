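task,LKNEx,LKNEy,LKNEz,CoMx,CoMy,CoMz
classic,1.53,1.43,2.05,2.11,1.44,1.3
jazz,1.43,1.13,2.57,2.04,1.79,1.69
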