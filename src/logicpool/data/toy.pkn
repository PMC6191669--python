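# Four-component toy network: input A drives the chain A -> B -> D;
# the regulation of C by D is uncertain (optional activation).
A -> A +
A -> B +
B -> D +
D -> C +?
function B = A
function D = B
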