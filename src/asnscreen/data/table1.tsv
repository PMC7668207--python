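id	organism	length	family
WP_053609500.1	S. purpurogeneiscleroticus	373	PF00710.11
WP_053610569.1	S. purpurogeneiscleroticus	338	PF00710.11
WP_055617501.1	S. phaeochromogenes	380	PF00710.11
WP_051815467.1	S. lavenduligriseus	363	PF00710.11
WP_078649241.1	S. fradiae	350	PF00710.11
EFL23513.1	S. himastatinicu ATCC 53653	351	PF00710.11
WP_014151616.1	S. cattleya	331	PF00710.11
WP_095730579.1	S. albidoflavus	333	PF00710.11
WP_078965752.1	S. aureocirculatus	343	PF00710.11
WP_078513220.1	S. purpureus	421	PF00710.11
WP_009718687.1	S. himastatinicus	347	PF00710.11
WP_079189481.1	S. paucisporeus	384	PF00710.11
WP_052425051.1	S. fulvoviolaceus	340	PF00710.11
ELP65653.1	S. turgidiscabies Car8	358	PF00710.11
WP_070201703.1	S. nanshensis	347	PF00710.11
KWW98572.1	S. thermoautotrophicus	333	PF00710.11
WP_073950513.1	S. kebangsaanensis	333	PF00710.11
WP_030748190.1	S. griseus	329	PF00710.11
WP_059134811.1	S. alboniger	332	PF00710.11
ARZ68596.1	S. albireticuli	428	PF06089.11
CDR15801.1	S. iranensis	387	PF06089.11
SOD64826.1	S. zhaozhouensis	316	PF06089.11
WP_020554088	S. scabrisporus	332	PF06089.11
WP_044373749	S. ahygroscopicus	330	PF06089.11
WP_078645645	S. varsoviensis	348	PF06089.11
WP_078980718.1	S. scabrisporus	327	PF06089.11
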