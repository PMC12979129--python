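MT1A
MT1E
MT1F
MT1G
MT1M
SLC30A1
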