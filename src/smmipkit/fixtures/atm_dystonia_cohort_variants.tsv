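patient_id	cdna_change	protein_change	consequence	intron_distance	af_1000g	af_exac	inhouse_count	cadd	classification
Dys1	c.115A>G	p.(Thr39Ala)	missense	0	0.002	0.0031	4	14.38	VUS
Dys2	c.670A>G	p.(Lys224Glu)	missense	0	0	0.0002	7	23.5	VUS
Dys3	c.670A>G	p.(Lys224Glu)	missense	0	0	0.0002	7	23.5	VUS
Dys4	c.1066-6T>G		intronic	6	0.004	0.006	21		VUS
Dys4	c.7618G>A	p.(Val2540Ile)	missense	0	0.001	0.0008	12	20.6	VUS
Dys5	c.1066-6T>G		intronic	6	0.004	0.006	21		VUS
Dys6	c.1066-6T>G		intronic	6	0.004	0.006	21		VUS
Dys7	c.2386A>T	p.(Asn796Tyr)	missense	0	0	0.0001	2	7.75	VUS
Dys8	c.3802G>A	p.(Val1268Met)	missense	0	0.0005	0.0009	9	26.9	VUS
Dys9	c.4060C>A	p.(Pro1354Thr)	missense	0	0	0	1	14.83	VUS
Dys10	c.4297T>G	p.(Tyr1433Asp)	missense	0	0	0.0001	3	27.3	VUS
Dys11	c.4388T>G	p.(Phe1463Cys)	missense	0	0.0008	0.0011	15	28.7	VUS
Dys12	c.4424A>G	p.(Tyr1475Cys)	missense	0	0	0.0003	5	18.12	VUS
Dys13	c.5005+7_5005+8delTA		intronic	7	0	0	2		VUS
Dys14	c.5693G>A	p.(Arg1898Gln)	missense	0	0.0021	0.0033	18	18.17	VUS
Dys15	c.5890A>G	p.(Lys1964Glu)	missense	0	0.0014	0.0019	11	17.81	VUS
Dys16	c.6860G>C	p.(Gly2287Ala)	missense	0	0	0.0002	6	10.23	VUS
Dys17	c.6983C>T	p.(Pro2328Leu)	missense	0	0.0003	0.0006	8	22.4	VUS
Dys18	c.7276C>T	p.(Leu2426Phe)	missense	0	0	0.0001	2	29.3	VUS
Dys19	c.7475T>G	p.(Leu2492Arg)	missense	0	0	0	1	28.3	VUS
Dys20	c.7796C>T	p.(Thr2599Ile)	missense	0	0.0018	0.0025	14	11.78	VUS
Dys21	c.8147T>C	p.(Val2716Ala)	missense	0	0	0.0001	3	26.2	5
Dys21	c.8578_8580delTCT	p.(Ser2860del)	inframe_indel	0	0	0	1		VUS
Dys22	c.8314G>A	p.(Gly2772Arg)	missense	0	0	0.0002	4	31	VUS
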