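# Discretized time series over B, C, D: B rises first, then C and D are
# jointly active; started from the all-off state with the input switched on.
ToyTS: EF(B=1&EF(C=1&D=1)) IS:A=1,B=0,C=0,D=0
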