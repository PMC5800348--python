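# Wet-lab CNV confirmation outcomes for the 550-individual IRD gene-panel study
# cohort: the input to PPV and diagnostic-yield computation.  The 44 confirmed
# events carry their published per-event annotations.  Tested-but-unconfirmed
# events (U01-U12 of the primary filter set; X01-X12 of the deliberately
# confirmed excluded set) were published only as counts, so those rows are
# synthetic placeholders carrying the outcome flags only.
sample_id	event_label	gene	type	zygosity	classification	diagnostic_contribution	tested	confirmed	group
15010656	TRPM1 whole gene	TRPM1	del	het	likely pathogenic	confirms	yes	yes	primary
14016924	PDE6B whole gene	PDE6B	del	het	likely pathogenic	confirms	yes	yes	primary
15000307	MERTK ex3-19	MERTK	del	het	likely pathogenic	confirms	yes	yes	primary
15010972	PCDH15 ex1-19	PCDH15	del	het	likely pathogenic	confirms	yes	yes	primary
15012122	KIF11 ex12-22	KIF11	del	het	likely pathogenic	confirms	yes	yes	primary
15006709	MERTK ex1-7	MERTK	del	het	likely pathogenic	confirms	yes	yes	primary
084929	RPE65 whole gene	RPE65	del	het	likely pathogenic	confirms	yes	yes	primary
15005941	USH2A ex10-14	USH2A	del	het	likely pathogenic	confirms	yes	yes	primary
15005265	EYS ex12-15	EYS	del	het	likely pathogenic	confirms	yes	yes	primary
14015843	CRB1 ex4-5	CRB1	del	het	likely pathogenic	confirms	yes	yes	primary
13011434	EYS ex33	EYS	del	hom	likely pathogenic	confirms	yes	yes	primary
15005668	CERKL ex1-2	CERKL	del	het	likely pathogenic	confirms	yes	yes	primary
15010867	CNGB3 ex9-10	CNGB3	del	het	likely pathogenic	confirms	yes	yes	primary
15005008	NMNAT1 ex3	NMNAT1	del	het	likely pathogenic	confirms	yes	yes	primary
12008422	USH2A ex34-35	USH2A	del	het	likely pathogenic	confirms	yes	yes	primary
14017566	CERKL ex1	CERKL	del	het	likely pathogenic	confirms	yes	yes	primary
15001263	USH2A ex47	USH2A	del	het	likely pathogenic	confirms	yes	yes	primary
15004859	RPGRIP1 ex20	RPGRIP1	del	het	likely pathogenic	confirms	yes	yes	primary
13001147	EYS ex31	EYS	del	het	likely pathogenic	confirms	yes	yes	primary
13006640	LRP5 ex11	LRP5	del	het	likely pathogenic	confirms	yes	yes	primary
14010419	CNGB1 ex20-23	CNGB1	del	hom	likely pathogenic	confirms	yes	yes	primary
12014502	CNGB1 ex20-23	CNGB1	del	hom	likely pathogenic	confirms	yes	yes	primary
14020104	MAK ex3	MAK	del	hom	likely pathogenic	confirms	yes	yes	primary
15010966	BBS2 ex4-5	BBS2	del	het	likely pathogenic	none	yes	yes	primary
14017272	BBS4 ex6-7	BBS4	del	het	likely pathogenic	none	yes	yes	primary
14021329	CDH3 ex12-13	CDH3	del	het	likely pathogenic	none	yes	yes	primary
15010313	CLN3 ex8-9	CLN3	del	het	likely pathogenic	none	yes	yes	primary
14016318	GRM6 ex2	GRM6	del	het	likely pathogenic	none	yes	yes	primary
13009597	IDH3B/MKKS whole genes	IDH3B/MKKS	del	het	likely pathogenic	none	yes	yes	primary
14009753	NPHP1 whole gene	NPHP1	del	het	likely pathogenic	none	yes	yes	primary
13013491	RGR ex3	RGR	del	het	uncertain significance	none	yes	yes	primary
043844	FSCN2 ex2	FSCN2	del	het	uncertain significance	none	yes	yes	primary
14020099	RP1L1 ex2-4	RP1L1	del	het	uncertain significance	none	yes	yes	primary
10003406	USH2A ex57-60	USH2A	dup	het	likely pathogenic	confirms	yes	yes	primary
13018538	EYS ex30	EYS	dup	hom	likely pathogenic	confirms	yes	yes	primary
14001342	EYS ex34-35	EYS	dup	het	uncertain significance	none	yes	yes	primary
14017670	PRPF31 ex2-8	PRPF31	dup	hom	uncertain significance	none	yes	yes	primary
15007281	BBS5 whole gene	BBS5	dup	het	uncertain significance	none	yes	yes	primary
15009450	RP9/BBS9	RP9/BBS9	dup	het	uncertain significance	none	yes	yes	primary
13009597	ZNF513-FAM161A multigene	ZNF513/C2orf71/EFEMP1/FAM161A	dup	het	uncertain significance	none	yes	yes	primary
14015751	NPHP1 whole gene	NPHP1	dup	het	likely benign	none	yes	yes	primary
14018818	NPHP1 whole gene	NPHP1	dup	het	likely benign	none	yes	yes	primary
15008560	NPHP1 whole gene	NPHP1	dup	het	likely benign	none	yes	yes	primary
15010871	CYP4V2 whole gene	CYP4V2	dup	het	likely benign	none	yes	yes	primary
U01	unconfirmed-01	NA	del	het	uncertain significance	none	yes	no	primary
U02	unconfirmed-02	NA	del	het	uncertain significance	none	yes	no	primary
U03	unconfirmed-03	NA	del	het	uncertain significance	none	yes	no	primary
U04	unconfirmed-04	NA	del	het	uncertain significance	none	yes	no	primary
U05	unconfirmed-05	NA	del	het	uncertain significance	none	yes	no	primary
U06	unconfirmed-06	NA	del	het	uncertain significance	none	yes	no	primary
U07	unconfirmed-07	NA	dup	het	uncertain significance	none	yes	no	primary
U08	unconfirmed-08	NA	dup	het	uncertain significance	none	yes	no	primary
U09	unconfirmed-09	NA	dup	het	uncertain significance	none	yes	no	primary
U10	unconfirmed-10	NA	dup	het	uncertain significance	none	yes	no	primary
U11	unconfirmed-11	NA	dup	het	uncertain significance	none	yes	no	primary
U12	unconfirmed-12	NA	dup	het	uncertain significance	none	yes	no	primary
14016366	NPHP1 whole gene	NPHP1	dup	het	likely benign	none	yes	yes	excluded_set
X01	excluded-01	NA	del	het	uncertain significance	none	yes	no	excluded_set
X02	excluded-02	NA	del	het	uncertain significance	none	yes	no	excluded_set
X03	excluded-03	NA	del	het	uncertain significance	none	yes	no	excluded_set
X04	excluded-04	NA	del	het	uncertain significance	none	yes	no	excluded_set
X05	excluded-05	NA	del	het	uncertain significance	none	yes	no	excluded_set
X06	excluded-06	NA	del	het	uncertain significance	none	yes	no	excluded_set
X07	excluded-07	NA	dup	het	uncertain significance	none	yes	no	excluded_set
X08	excluded-08	NA	dup	het	uncertain significance	none	yes	no	excluded_set
X09	excluded-09	NA	dup	het	uncertain significance	none	yes	no	excluded_set
X10	excluded-10	NA	dup	het	uncertain significance	none	yes	no	excluded_set
X11	excluded-11	NA	dup	het	uncertain significance	none	yes	no	excluded_set
X12	excluded-12	NA	dup	het	uncertain significance	none	yes	no	excluded_set
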