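gene	role	chrom	start	end	length_bp
TP53	TSG	17	7571720	7590868	19149
MDM2	oncogene	12	69201956	69244466	42511
MDM4	oncogene	1	204485511	204527248	41738
ATM	TSG	11	108093211	108239829	146619
CHEK2	TSG	22	29083731	29137822	54092
KRAS	oncogene	12	25358180	25403854	45675
EGFR	oncogene	7	55086725	55275031	188307
BRAF	oncogene	7	140433813	140624564	190752
NF1	TSG	17	29421945	29709134	287190
ERBB2	oncogene	17	37844393	37884915	40523
RET	oncogene	10	43572475	43625799	53325
PIK3CA	oncogene	3	178866311	178952497	86187
PTEN	TSG	10	89623195	89728532	105338
AKT1	oncogene	14	105235686	105262088	26403
STK11	TSG	19	1205798	1228431	22634
TSC2	TSG	16	2097990	2138713	40724
APC	TSG	5	112043202	112181936	138735
CTNNB1	oncogene	3	41236328	41301587	65260
AXIN1	TSG	16	337440	402673	65234
RB1	TSG	13	48877887	48921101	43215
CDKN2A	TSG	9	21967751	21995300	27550
CCND1	oncogene	11	69455873	69469242	13370
CDK4	oncogene	12	58141510	58149796	8287
MYC	oncogene	8	128748315	128753680	5366
NFE2L2	oncogene	2	178095031	178129859	34829
KEAP1	TSG	19	10596796	10614417	17622
NOTCH1	both	9	139388896	139440238	51343
NOTCH2	both	1	120454176	120612317	158142
FBXW7	TSG	4	153242410	153456185	213776
NF2	TSG	22	29999545	30094589	95045
FAT1	TSG	4	187508937	187644987	136051
SMAD4	TSG	18	48556583	48611411	54829
SMAD2	TSG	18	45359466	45456970	97505
TGFBR2	TSG	3	30647994	30735634	87641
VHL	TSG	3	10183319	10195354	12036
BAP1	TSG	3	52435029	52444366	9338
PBRM1	TSG	3	52579368	52719866	140499
SETD2	TSG	3	47057898	47205467	147570
MAP2K4	TSG	17	11924141	12047147	123007
NCOR1	TSG	17	15932544	16121610	189067
SMARCA4	TSG	19	11071598	11176071	104474
CYLD	TSG	16	50775961	50835846	59886
ARID1B	TSG	6	157099063	157531913	432851
LRP1B	TSG	2	140988992	142889270	1900279
KMT2C	TSG	7	151832010	152133090	301081
ESR1	oncogene	6	152011631	152424408	412778
MUC6	other	11	1012823	1036706	23884
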