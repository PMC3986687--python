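name,st_weight,st_duration_years,fraction_long_term,lt_weight,is_fatal,comment
Concussion,0.359,0.0671,0.05,0.35,0,Intracranial injuries
Poisoning,0.611,0.0082,0,0,0,Poisoning
Spinal injury,0.725,0,1,0.725,0,Injured spinal cord
Sprained or twisted,0.064,0.0384,0,0,0,Sprains
Other internal injury,0.208,0.0425,0,0,0,Internal injuries
Respiratory infection,0.07,0.02,0,0,0,Upper respiratory infections - pharyngitis
Heart attack,0.323,0.1,0.2,0.353,0,Rheumatic heart disease and heart failure
Aches or pains,0.02,0.02,0,0,0,
Electric shock minor,0.04,0.02,0,0,0,
Electric shock severe,0.2,0.1,0.1,0.15,0,
External bruise,0.04,0.02,0,0,0,
Swelling,0.04,0.02,0,0,0,
Whiplash,0.04,0.02,0.05,0.04,0,
Fatal injury,0,0,1,1,1,
No Injury,0,0,0,0,0,
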