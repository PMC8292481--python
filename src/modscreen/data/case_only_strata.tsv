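stratum	unexposed_hom_ref	unexposed_het	unexposed_hom_alt	exposed_hom_ref	exposed_het	exposed_hom_alt	pub_or	pub_ci_low	pub_ci_high	pub_p	discrepancy	note
SWEA1	549	138	16	60	5	2	0.46	0.17	1.04	0.053	or,ci,p	exposed triplet printed as 0-5-2 but group percentages (90%-7%-3%) and the stated 67 genotyped carriers imply 60-5-2; published statistics are not reproducible from either reading
SWEA2	73	14	0	34	11	0	1.68	0.62	4.47	0.25
Helsinki1-unselected	1432	232	9	44	4	0	0.54	0.14	1.50	0.30		narrative quotes 688 unexposed cases while the printed triplet sums differ; triplet kept as printed
Helsinki1-additional-familial	603	99	3	45	4	1	0.66	0.20	1.71	0.53
Helsinki2	841	119	5	26	2	0	0.52	0.06	2.13	0.57	p	published P 0.57; Fisher exact on the printed triplets gives 0.565
Tampere	564	87	1	12	2	0	1.10	0.11	4.92	1.00	or	published OR 1.10; neither the sample OR (1.068) nor the conditional MLE (1.068) reproduces it
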