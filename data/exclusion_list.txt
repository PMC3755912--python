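# ORFs excluded from parameter extraction (abnormal size profiles),
# one identifier per line. Empty template: populate after curating
# the source dataset.
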