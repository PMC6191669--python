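# Experimental observations encoded as CTL (Western blot and Bio-Plex series,
# both cell lines, DMSO vs Sorafenib treatment).
WB.DMSO: EF(AG(mTORC1=1)) IS:Sora=0
WB1257Sora: EF(AG(mTORC1=0)) IS:Sora=1
WB1851Sora: EF(AG(mTORC1=1)) IS:Sora=1
Bp1851Sora: EF(mTor=1&Akt=0&EGFR=0&Erk=0&IGFR=1&EF(mTor=1&Akt=1&EGFR=1&Erk=1&IGFR=1&EF(mTor=0&Akt=0&EGFR=0&Erk=0&IGFR=1)))IS:Sora=1
Bp1851DMSO: EF(mTor=1&Akt=1&EGFR=1&Erk=1&IGFR=1&EF(mTor=1&Akt=1&EGFR=1&Erk=1&IGFR=0&EF(mTor=1&Akt=0&EGFR=1&Erk=1&IGFR=0&EF(mTor=0&Akt=0&EGFR=0&Erk=0&IGFR=0))))IS:Sora=0
Bp1851Sora2: EF(mTor=1&Akt=1&EGFR=1&Erk=1&IGFR=1&EF(mTor=0&Akt=1&EGFR=1&Erk=1&IGFR=1&EF(mTor=1&Akt=1&EGFR=1&Erk=1&IGFR=0&EF(mTor=1&Akt=0&EGFR=0&Erk=0&IGFR=0&EF(mTor=0&Akt=0&EGFR=1&Erk=1&IGFR=0&EF(mTor=1&Akt=0&EGFR=1&Erk=1&IGFR=1))))))IS:Sora=1
Bp1851DMSO2: EF(mTor=1&Akt=1&EGFR=1&Erk=1&IGFR=0&EF(mTor=0&Akt=1&EGFR=0&Erk=1&IGFR=0&EF(mTor=0&Akt=0&EGFR=0&Erk=1&IGFR=0&EF(mTor=1&Akt=1&EGFR=1&Erk=1&IGFR=0&EF(mTor=0&Akt=0&EGFR=0&Erk=0&IGFR=0&EF(mTor=0&Akt=0&EGFR=1&Erk=1&IGFR=0&EF(mTor=1&Akt=1&EGFR=1&Erk=1&IGFR=0)))))))IS:Sora=0
Bp1257Sora: EF(mTor=1&Akt=1&EGFR=1&Erk=1&EF(mTor=0&Akt=0&EGFR=0&Erk=0&EF(mTor=0&Akt=0&EGFR=1&Erk=0&EF(mTor=1&Akt=1&EGFR=1&Erk=1&EF(mTor=0&Akt=0&EGFR=1&Erk=0&EF(mTor=1&Akt=0&EGFR=1&Erk=1))))))IS:Sora=1
Bp1257DMSO: EF(Delta=0&mTor=1&Akt=1&EGFR=1&Erk=1)IS:Sora=0
Bp1257Sora2: EF(mTor=0&Akt=0&EGFR=0&Erk=0&EF(mTor=0&Akt=1&EGFR=0&Erk=0&EF(mTor=1&Akt=1&EGFR=1&Erk=1&EF(mTor=1&Akt=1&EGFR=1&Erk=0&EF(mTor=1&Akt=0&EGFR=1&Erk=1&EF(mTor=1&Akt=1&EGFR=1&Erk=1))))))IS:Sora=1
Bp1257DMSO2: EF(mTor=1&Akt=0&EGFR=1&Erk=1&EF(mTor=1&Akt=0&EGFR=1&Erk=0&EF(mTor=1&Akt=1&EGFR=1&Erk=1&EF(mTor=0&Akt=0&EGFR=0&Erk=0&EF(mTor=1&Akt=1&EGFR=1&Erk=1)))))IS:Sora=0
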