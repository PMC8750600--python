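feature	T01	T02	T03	T04	T05	T06	T07	T08	T09	T10	T11	T12	T13	T14	T15
G01	5.1	6.2	4.8	7.3	5.5	6.1	4.9	5.8	6.4	5.2	7.1	6.6	5.9	6.0	5.4
G02	3.2	4.1	3.8	3.5	4.4	3.9	4.2	3.6	4.0	3.7	4.3	3.4	4.5	3.3	4.6
G03	2.5	2.8	3.1	2.9	3.3	2.6	NA	3.0	2.7	3.2	2.4	3.4	2.3	3.5	2.2
G04	5.0	4.0	6.0	5.5	0.5	0.4	0.6	0.3	0.7	0.5	0.4	0.6	0.5	0.3	0.7
G05	2.0	2.2	2.1	2.3	2.4	2.5	2.6	2.7	2.8	2.9	3.0	3.1	3.2	3.3	3.4
G06	2.0	2.1	2.2	2.3	2.4	0.5	0.6	0.7	0.8	0.9	0.5	0.6	0.7	0.8	0.9
G07	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0
G08	1.5	2.5	3.5	4.5	5.5	6.5	7.5	8.5	9.0	8.0	7.0	6.0	5.0	4.0	3.0
G09	9.1	8.2	7.3	6.4	5.5	4.6	3.7	2.8	1.9	2.9	3.9	4.9	5.9	6.9	7.9
G10	3.1	3.2	3.3	3.4	3.5	0.9	0.8	0.7	0.6	0.5	0.9	0.8	0.7	0.6	0.5
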