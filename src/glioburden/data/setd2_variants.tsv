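sample_id	gene	chrom	pos	ref	alt	consequence	sift	polyphen	conserved	in_population_db	in_control_exomes
T0001	SETD2	3	47100001	C	T	frameshift	unknown	unknown	0	0	0
T0002	SETD2	3	47105002	C	T	frameshift	unknown	unknown	0	0	0
T0003	SETD2	3	47110003	C	T	frameshift	unknown	unknown	0	0	0
T0004	SETD2	3	47115004	C	T	nonsense	unknown	unknown	0	0	0
T0005	SETD2	3	47120005	C	T	splice_site	unknown	unknown	0	0	0
T0006	SETD2	3	47125006	C	T	missense	damaging	damaging	1	0	0
T0007	SETD2	3	47130007	C	T	missense	damaging	damaging	1	0	0
T0008	SETD2	3	47135008	C	T	missense	damaging	damaging	1	0	0
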