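# The unaudited research world: selection alone, competitive spiral
# in essentially every replicate.
audits: none
cycles: 800000
record_every: 8000
replicates: 500
seed: 1
label: no_audits
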