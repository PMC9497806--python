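task,LKNEx,LKNEy,LKNEz,CoMx,CoMy,CoMz
classic,0.75,0.71,0.71,0.75,0.72,0.70
jazz,0.76,0.66,0.70,0.73,0.69,0.75
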