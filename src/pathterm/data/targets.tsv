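designation	snomed_code	axis	approximate
Cell	362837007	cell structure	0
Disease	64572001	disorder	0
Lesion	49755003	morphologic abnormality	0
Margin	82868003	body structure	0
Mitotic nucleus	49307000	cell structure	0
Nucleolus	15982001	cell structure	0
Nucleus	84640000	cell structure	0
Organ	272625005	body structure	0
Specimen	123038009	specimen	0
Tissue	85756007	body structure	0
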