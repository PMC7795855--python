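miR_name	miR_direction	transcript	transcript_direction	tissue	degradome_detection
mtr-miR408-3p_L-1R+1	up	Bv6_144730_qgsa.t1	down	leaf	Y
mtr-miR408-3p_L-1R+1	up	Bv1_023200_jmkt.t1	down	leaf	Y
gma-miR408a-3p_L-1R+5	up	Bv1_023200_jmkt.t1	down	leaf	Y
PC-3p-154_19269	up	Bv6_136680_juie.t1	down	leaf	Y
PC-3p-154_19269	up	Bv6_136690_fscn.t1	down	leaf	Y
mtr-miR395a_L-1	down	Bv_009820_mrec.t1	up	leaf	Y
mtr-miR395k_1ss1TC	down	Bv_009820_mrec.t1	up	leaf	Y
gma-miR403a_1ss20TC	down	Bv4_094840_csri.t1	up	leaf	Y
mtr-miR395a_L-1	down	Bv_010680_tsww.t1	up	leaf	N
lus-MIR396e-p5	down	Bv1_015660_nghm.t1	up	leaf	N
PC-3p-726_3835	down	MSTRG.2715.1	up	leaf	N
PC-5p-109182_51	down	Bv4_078360_ftyu.t1	up	leaf	N
PC-5p-36464_148	down	Bv1_011830_oexd.t1	up	leaf	N
PC-5p-3682_979	down	Bv5_114160_hsdp.t1	up	leaf	N
PC-5p-3682_979	down	Bv8_193090_kary.t1	up	leaf	N
PC-5p-49652_112	down	MSTRG.29155.1	up	leaf	N
csi-miR156a-5p_R+1_1ss9GT	up	Bv6_136190_cygi.t1	down	root	Y
mtr-miR164d	up	Bv5_114390_pjnp.t1	down	root	Y
PC-5p-7955_523	up	Bv5_124210_skcr.t1	down	root	Y
gma-miR6300_L-1R+1	up	Bv5_097930_juac.t1	down	root	N
gma-miR6300_L-1R+1	up	Bv5_100510_ttjr.t1	down	root	N
gma-miR6300_L-1R+1	up	Bv9_208900_gijo.t1	down	root	N
PC-5p-3682_979	up	Bv1_012390_utfq.t1	down	root	N
PC-5p-3682_979	up	Bv1_017030_kxfa.t1	down	root	N
PC-5p-3682_979	up	Bv5_117790_mxei.t1	down	root	N
PC-5p-3682_979	up	Bv6_132150_dsqx.t1	down	root	N
PC-5p-3682_979	up	Bv6_135930_aphq.t1	down	root	N
PC-5p-3682_979	up	Bv8_193090_kary.t1	down	root	N
ptc-miR399e	down	Bv5_121080_kswa.t1	up	root	N
PC-5p-109182_51	down	Bv5_110660_jxri.t1	up	root	N
PC-5p-109182_51	down	Bv9_213960_qddk.t1	up	root	N
PC-5p-130970_42	down	MSTRG.29564.3	up	root	N
PC-5p-36464_148	down	MSTRG.25036.1	up	root	N
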