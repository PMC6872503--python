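timepoint	unit_id	p_value
baseline	2	0.0463
baseline	18	0.0005
m06	8	0.0182
m06	14	0.0108
m06	17	0.0155
m06	18	0.0010
m12	6	0.0117
m12	14	0.0018
m12	17	0.0107
m12	18	<0.00005
m24	0	0.0245
m24	3	0.0133
m24	5	0.0092
m24	7	0.0063
m24	8	0.0030
m24	9	0.0007
m24	11	0.0084
m24	12	0.0002
m24	13	0.0082
m24	14	<0.00005
m24	15	0.0098
m24	17	0.0239
m24	18	<0.00005
m24	19	0.0210
m24	21	0.0363
m24	22	0.0166
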