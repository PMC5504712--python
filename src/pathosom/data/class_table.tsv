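code	class	subclass	subclass2
1100	Description	Definition
1400	Description	System/Lokalisation
1500	Description	Struktur	ElementOf
1540	Description	Struktur	HasElement
1550	Description	Struktur	HasVariante
1570	Description	Struktur	Sekundare Form
5100	Symptoms	Anamnese
5110	Symptoms	Anamnese	Akut
5130	Symptoms	Anamnese	Vorgeschichte
5140	Symptoms	Anamnese	Familie
5150	Symptoms	Anamnese	Demografisch
5160	Symptoms	Anamnese	Sozial
5300	Symptoms	Vital
5400	Symptoms	Physikal
5410	Symptoms	Physikal	Spirometry
5500	Symptoms	Labor
5510	Symptoms	Labor	Clinical
5520	Symptoms	Labor	Agent
5530	Symptoms	Labor	Toxicology
5600	Symptoms	Imaging
5610	Symptoms	Imaging	Ultrasound
5620	Symptoms	Imaging	Radiology
5630	Symptoms	Imaging	MRT
5640	Symptoms	Imaging	CT
5650	Symptoms	Imaging	Endoskopie
5700	Symptoms	Pathologie
5710	Symptoms	Pathologie	Makroskopie
5720	Symptoms	Pathologie	Mikroskopie
5725	Symptoms	Pathologie	Elektronenmikroskopie
5730	Symptoms	Pathologie	Spezialfarbung
5735	Symptoms	Pathologie	Enzymhistochemie
5738	Symptoms	Pathologie	Zytologie
5740	Symptoms	Pathologie	Immunhistochemie
5745	Symptoms	Pathologie	FACS
5750	Symptoms	Pathologie	In-Situ Hybridisierung
5760	Symptoms	Pathologie	Molekularbiologie
5770	Symptoms	Pathologie	Stoffe
5795	Symptoms	Pathologie	Differenzialdiagnose
5800	Symptoms	Genetik
5900	Symptoms	Psychologie
6100	Characteristics	Historie
6300	Characteristics	Epidemologie
6310	Characteristics	Epidemologie	Sex
6320	Characteristics	Epidemologie	Age
6330	Characteristics	Epidemologie	Race
6340	Characteristics	Epidemologie	Region
6350	Characteristics	Epidemologie	Inzidenz
6360	Characteristics	Epidemologie	Pravalenz
6400	Characteristics	Atiologie
6500	Characteristics	Pathophysiologie
6600	Characteristics	Verlauf
6610	Characteristics	Verlauf	Beginn
6620	Characteristics	Verlauf	Verlauf
6630	Characteristics	Verlauf	Stadium
6640	Characteristics	Verlauf	Prognose
6650	Characteristics	Verlauf	Komplikation
6660	Characteristics	Verlauf	Risikofaktor
6700	Characteristics	Komorbiditat
6800	Characteristics	Differentialdiagnose
6900	Characteristics	Untersuchung
8100	Therapy	Therapieprinzipien
8200	Therapy	Medikamente
8300	Therapy	Chirurgie
8400	Therapy	Strahlentherapie
8500	Therapy	Ambulance
8600	Therapy	ReHa
8700	Therapy	Psychotherapie
8800	Therapy	Alternative
9800	Therapy	Vorsorge
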