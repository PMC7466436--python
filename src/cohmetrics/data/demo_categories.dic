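%
20	differentiation
21	conjunctions
%
wenn 20
aber 20
doch 20
obwohl 20
wenngleich 20
und 21
oder 21
denn 21
sowie 21
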