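id	epitope_number	cpr_value	allele_number	ed
P00805_EcAII	10	0.6383	5	0.0114
WP_053609500.1	12	0.5174	5	0.0171
WP_053610569.1	14	0.5381	8	0.0196
WP_055617501.1	7	0.4532	7	0.0112
WP_051815467.1	6	0.6673	5	0.0060
WP_078649241.1	7	0.4554	6	0.0111
EFL23513.1	10	0.6054	8	0.0115
WP_014151616.1	3	0.4024	5	0.0056
WP_095730579.1	8	0.5346	2	0.0115
WP_078965752.1	3	0.4987	4	0.0045
WP_078513220.1	9	0.4551	6	0.0119
WP_009718687.1	5	0.6480	4	0.0052
WP_079189481.1	4	0.5217	5	0.0051
WP_052425051.1	10	0.4369	6	0.0170
ELP65653.1	5	0.6717	3	0.0047
WP_070201703.1	7	0.6637	6	0.0069
KWW98572.1	4	0.7254	4	0.0034
WP_073950513.1	6	0.7424	4	0.0048
WP_030748190.1	3	0.5125	6	0.0046
Q9K4F5_ScAII	3	0.4167	3	0.0053
ARZ68596.1	5	0.6283	5	0.0044
SOD64826.1	5	0.5046	5	0.0080
WP_078645645.1	7	0.6404	5	0.0074
CDR15801.1	5	0.5510	5	0.0059
WP_078980718.1	6	0.7003	6	0.0056
WP_044373749.1	3	0.7114	4	0.0027
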