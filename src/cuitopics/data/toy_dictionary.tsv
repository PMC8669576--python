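# Toy concept dictionary (synthetic stand-in for a UMLS-derived dictionary).
# Columns: cui	category	surface
C0030193	SignSymptom	pain
C0004604	SignSymptom	back pain
C0015672	SignSymptom	fatigue
C0015672	SignSymptom	exhausted
C0003467	SignSymptom	anxiety
C0038999	SignSymptom	swelling
C0013604	DiseaseDisorder	swelling
C0021368	DiseaseDisorder	inflammation
C0006142	DiseaseDisorder	breast cancer
C0006142	DiseaseDisorder	breast carcinoma
C0021311	DiseaseDisorder	infection
C0040808	Procedure	removal
C0520966	Procedure	implant removal
C0006141	Anatomy	breast
C0020740	Medication	ibuprofen
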