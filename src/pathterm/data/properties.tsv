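designation	snomed_code	axis	approximate
Area	42798000	qualifier value	0
Class	277046005	attribute	0
Colour	263714004	qualifier value	0
Consistency	246191002	attribute	0
CytologicAtypia	50673007	morphologic abnormality	0
Diameter	81827009	qualifier value	0
Distance	246132006	qualifier value	0
General clinical stage for disease AND/OR neoplasm	106240007	qualifier value	0
Grade	103421006	attribute	0
Involvement	278112009	attribute	0
MarkerStatus	246110002	attribute	0
Measurement	122869004	procedure	0
NeighborhoodRelationship	408739003	attribute	1
Number	410680006	attribute	0
Pattern	255711007	attribute	0
Regularity	246202005	attribute	0
ResidualDisease	65320000	qualifier value	0
Shape	300842002	attribute	0
Size	246115007	attribute	0
SpecificDeposits	46595003	morphologic abnormality	0
TreatmentEffect	253861007	qualifier value	1
Weight	272102008	qualifier value	0
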