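v1	v2
v1	v3
v1	v8
v1	v9
v2	v6
v2	v9
v3	v6
v3	v7
v3	v8
v4	v5
v4	v8
v4	v9
v4	v10
v5	v6
v5	v7
v6	v7
v6	v8
v7	v8
v7	v9
v8	v10
v9	v10
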