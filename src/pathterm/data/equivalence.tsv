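oid	is_example	pattern	generic_element	family	extra_patterns	target	property	method	qualifiers	note
1.3.6.1.4.1.19376.1.8.1.4.54	1	Cytological type	Class	staging_grading_classification	Histological type|classification|category|type	Lesion	Class	ObservedByMicroscopicInvestigation
1.3.6.1.4.1.19376.1.8.1.4.164	1	Lesion size, largest dimension	Diameter	core_generic	Lesion size|Tumour size	Lesion	Diameter	ObservedByMicroscopicInvestigation		worked example cites OID 1.3.6.1.4.1.49376.1.8.1.4.442; the 49376 arc diverges from the 19376 branch used elsewhere and is recorded uncorrected
1.3.6.1.4.1.19376.1.8.1.4.146	0	Distance of lesion from closest uninvolved margin	Distance	core_generic	Distance	Lesion	Distance	ObservedByMicroscopicInvestigation
1.3.6.1.4.1.19376.1.8.1.4.162	0	Treatment effect	Treatment Effect	core_generic		Lesion	TreatmentEffect	ObservedByMicroscopicInvestigation
1.3.6.1.4.1.19376.1.8.1.4.149	0	Extent	Extent	core_generic		Lesion	Size	ObservedByMicroscopicInvestigation
1.3.6.1.4.1.19376.1.8.1.4.143	0	Lesion focality	Focality	core_generic	Focality	Lesion	Number	ObservedByMicroscopicInvestigation	Focality	Focality doubles as a qualifier; the equivalence row is its alias
1.3.6.1.4.1.19376.1.8.1.4.151	1	Histological grade (WHO)	Grade	staging_grading_classification	grade|grading|score	Lesion	Grade	ObservedByMicroscopicInvestigation
1.3.6.1.4.1.19376.1.8.1.4.168	0	Macroscopic type	Growth pattern	core_generic	growth pattern	Lesion	Pattern	ObservedByMacroscopicInvestigation
1.3.6.1.4.1.19376.1.8.1.4.174	0	Specimen integrity	Integrity	core_generic		Specimen	Class	ObservedByMacroscopicInvestigation
1.3.6.1.4.1.19376.1.8.1.4.141	1	Margins involvement	Involvement	core_generic	margin involvement	Margin	Involvement	ObservedByMicroscopicInvestigation
1.3.6.1.4.1.19376.1.8.1.4.439	1	Estrogen receptor	Marker	marker	receptor|expression|mutation|marker	Tissue	MarkerStatus	ObservedByMicroscopicInvestigation
1.3.6.1.4.1.19376.1.8.1.4.318	1	Lesion ulceration	Neighborhood relationship	core_generic	ulceration	Lesion	NeighborhoodRelationship	ObservedByMicroscopicInvestigation
1.3.6.1.4.1.19376.1.8.1.4.156	1	Number of lymph nodes involved	Number	core_generic	Number of	Lesion	Number	ObservedByMicroscopicInvestigation
1.3.6.1.4.1.19376.1.8.1.4.148	1	Lymph node sampling	Procedure	procedure	sampling|biopsy|excision	Specimen	Measurement			procedures remain a classification category; this row covers observation templates phrased as procedures
1.3.6.1.4.1.19376.1.8.1.4.169	1	Lesion site	Site	core_generic	site|location	Lesion	Class	ObservedByMacroscopicInvestigation
1.3.6.1.4.1.19376.1.8.1.4.161	1	pT	Stage	staging_grading_classification	pN|pM|ypT|ypN|ypM|stage	Lesion	General clinical stage for disease AND/OR neoplasm	ObservedByMicroscopicInvestigation
1.3.6.1.4.1.19376.1.8.1.4.160	0	Specimen weight	Weight	core_generic		Specimen	Weight	ObservedByMacroscopicInvestigation
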