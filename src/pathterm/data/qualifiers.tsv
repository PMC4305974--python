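designation	snomed_code	axis	approximate
Laterality	272741003	attribute	0
Focality			0
Invasiveness	10179008	qualifier value	0
ScaleType	370132008	attribute	0
normalStructure	361083003	body structure	0
abnormalStructure	49755003	morphologic abnormality	0
specialAttributes			0
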