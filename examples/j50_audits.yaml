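# False-positive audits every 50 cycles (the most intensive published
# audit scenario); all omitted keys take their baseline values.
j: 50
n: 50
el_plus: 5
en_plus: 5
c: 0.67
review_error: 0
audits: false_positives
cycles: 800000
record_every: 8000
replicates: 500
seed: 1
label: j50_baseline
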