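spot_id
s1
s2
s3
s4
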