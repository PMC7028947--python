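label	cb_altered	cb_total	ncb_altered	ncb_total	printed_p
HR_pathway	7	24	1	38	0.004
NER_pathway	5	24	1	38	0.029
ERBB3	6	24	2	38	0.047
MSH6	4	24	0	38	0.019
BRCA1	3	24	0	38	0.054
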