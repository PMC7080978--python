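pt_name,smq_name,scope
Parkinson's disease,Parkinson-like events,narrow
Parkinsonism,Parkinson-like events,narrow
Bradykinesia,Parkinson-like events,narrow
Akinesia,Parkinson-like events,narrow
Cogwheel rigidity,Parkinson-like events,narrow
Hypertonia,Parkinson-like events,broad
Tremor,Parkinson-like events,broad
Gait disturbance,Parkinson-like events,broad
Dementia,Dementia,narrow
Dementia Alzheimer's type,Dementia,narrow
Vascular dementia,Dementia,narrow
Cognitive disorder,Dementia,broad
Memory impairment,Dementia,broad
Confusional state,Dementia,broad
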