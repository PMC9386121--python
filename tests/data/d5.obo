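format-version: 1.2
default-namespace: biological_process

[Term]
id: R
name: demo root

[Term]
id: A
name: demo branch a
is_a: R

[Term]
id: B
name: demo branch b
is_a: R

[Term]
id: C
name: demo leaf under a
is_a: A

[Term]
id: D
name: demo part of a
relationship: part_of A
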