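# Verbal-filler starting list (documented, overridable).
ähm
äh
hm
hmm
mhm
öhm
ne
nä
halt
tja
naja
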