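v1	v2
v1	v6
v1	v15
v2	v4
v2	v5
v2	v9
v2	v14
v2	v15
v2	v19
v3	v5
v3	v6
v3	v13
v3	v20
v4	v11
v4	v14
v4	v15
v5	v10
v5	v20
v6	v7
v6	v8
v6	v10
v6	v16
v7	v10
v7	v13
v7	v16
v7	v18
v8	v12
v8	v16
v8	v17
v9	v10
v10	v12
v10	v16
v11	v17
v12	v16
v13	v14
v13	v16
v13	v18
v13	v20
v14	v15
v14	v16
v15	v16
v15	v17
v15	v18
v16	v17
v16	v18
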