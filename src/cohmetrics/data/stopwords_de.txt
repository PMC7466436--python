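# German function-word starting list; fully overridable via PreprocessConfig.
aber
alle
als
also
am
an
auch
auf
aus
bei
bin
bis
bist
da
damit
dann
das
dass
dem
den
denn
der
des
die
doch
dort
du
durch
ein
eine
einem
einen
einer
eines
er
es
für
habe
haben
hat
hatte
hier
ich
ihr
im
in
ist
ja
kann
man
mein
mich
mir
mit
nach
nein
nicht
noch
nun
nur
oder
schon
sein
sich
sie
sind
so
über
um
und
uns
von
vor
war
waren
was
wenn
werden
wie
wieder
wir
wird
wo
zu
zum
zur
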