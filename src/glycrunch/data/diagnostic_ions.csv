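residue_class,mz,description
Neu5Ac,290.0881,"Neu5Ac B1 ion [M-H]- (negative mode oxocarbenium-type)"
Neu5Gc,306.0831,"Neu5Gc B1 ion [M-H]-"
dHex,145.0506,"Fuc B1 ion [M-H]-"
Kdn,249.0616,"Kdn B1 ion [M-H]-"
S,96.9601,"hydrogen sulfate anion HSO4-"
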