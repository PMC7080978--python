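# Demo study configuration; `input` and `dictionary` are resolved relative
# to the working directory at run time (see README tutorial).
input: reports.jsonl
dialect: jsonl
dictionary: smq_demo.csv
drugs: [ranibizumab, aflibercept]
route: intravitreal
smqs: [Parkinson-like events, Dementia]
scope: narrow
pt_level: true
period: [2010-01-01, 2016-12-31]
min_cases: 3
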