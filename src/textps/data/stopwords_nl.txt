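de
het
een
en
van
ik
te
dat
die
in
is
op
niet
met
zijn
er
maar
om
aan
voor
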