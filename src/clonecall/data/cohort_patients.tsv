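patient_id	diagnosis	populations
MS-1	Multiple sclerosis	CD4+;CD8+;CD19+
MS-2	Multiple sclerosis	CD4+;CD8+;CD19+;others
MS-3	Multiple sclerosis	CD4+;CD8+;CD19+;others
MS-4	Multiple sclerosis	CD4+;CD8+;CD19+;others
MG-5	Myasthenia gravis	CD4+;CD8+;CD19+;others
SP-6	Stiff-person syndrome	CD4+;CD8+;others
MS-7	Multiple sclerosis	CD4+;CD8+;CD19+;others
MS-8	Multiple sclerosis	CD4+;CD8+;CD19+;others
NL-9	Narcolepsy	CD4+;CD8+;CD19+;others
MS-10	Multiple sclerosis	CD4+;CD8+;CD19+;others
MS-11	Multiple sclerosis	CD4+;CD8+;CD19+;others
MS-12	Multiple sclerosis	CD4+;CD8+;CD19+;others
MS-14	Multiple sclerosis	CD4+;CD8+;CD19+
NL-16	Narcolepsy	CD4+;CD8+;CD19+
MS-17	Multiple sclerosis	CD4+;CD8+;CD19+
MS-19	Multiple sclerosis	CD4+;CD8+;CD19+
MS-21	Multiple sclerosis	CD4+;CD8+;CD19+
MS-22	Multiple sclerosis	CD4+;CD8+;CD19+
MS-23	Multiple sclerosis	CD4+;CD8+;CD19+
MS-24	Multiple sclerosis	CD4+;CD8+;CD19+
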