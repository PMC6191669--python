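# Growth-factor signaling in renal cancer cells: MAPK cascade (EGF/EGFR/Raf/Erk)
# and PI3K-mTORC1 branch (IGF/IGFR/PI3K/Akt/mTORC1) with the drug Sorafenib as
# an extra input.  Essential backbone edges; optional edges cover the three
# candidate Sorafenib targets, three pathway crosstalks, and the
# mTORC1 -> IGFR feedback relaxed because of the mTOR mutation.
Sora -> Sora +
EGF -> EGF +
IGF -> IGF +
EGF -> EGFR +
IGF -> IGFR +
EGFR -> Raf +
Raf -> Erk +
IGFR -> PI3K +
PI3K -> Akt +
Akt -> mTORC1 +
Erk -> EGFR -
Sora -> EGFR -?
Sora -> IGFR -?
mTORC1 -> IGFR -?
Sora -> Raf -?
PI3K -> Raf +?
EGFR -> PI3K +?
Erk -> mTORC1 +?
function Erk = Raf
function Akt = PI3K
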