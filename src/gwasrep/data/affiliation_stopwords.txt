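the
of
and
for
a
an
at
in
on
to
de
del
della
di
du
la
le
les
der
die
das
und
fur
van
von
het
voor
och
e
y
i
im
zu
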