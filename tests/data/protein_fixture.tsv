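feature	T01	T02	T03	T04	T05	T06	T07	T08	T09	T10	T11	T12	T13	T14	T15
G01	4.2	5.1	3.9	6.2	4.6	5.3	4.1	4.9	5.5	4.3	6.1	5.7	5.0	5.2	4.5
G02	2.8	3.6	NA	3.1	3.9	3.4	3.7	3.2	3.5	3.3	3.8	3.0	4.0	2.9	4.1
G03	2.1	2.4	2.7	2.5	2.9	2.2	2.8	2.6	2.3	2.8	2.0	3.0	1.9	3.1	1.8
G04	5.2	5.3	5.4	5.5	5.6	5.7	5.8	5.9	6.0	6.1	6.2	6.3	6.4	6.5	6.6
G05	3.1	3.2	3.3	0.2	0.3	0.2	0.3	0.2	0.3	0.2	0.3	0.2	0.3	0.2	0.3
G06	1.8	1.9	2.0	2.1	2.2	0.4	0.5	0.6	0.7	0.8	0.4	0.5	0.6	0.7	0.8
G07	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0
G08	2.1	3.1	4.1	5.1	6.1	7.1	8.1	9.1	9.5	8.5	7.5	6.5	5.5	4.5	3.5
G09	8.8	7.9	7.0	6.1	5.2	4.3	3.4	2.5	1.6	2.6	3.6	4.6	5.6	6.6	7.6
G10	2.6	2.7	2.8	2.9	0.9	0.8	0.7	0.6	0.5	0.4	0.9	0.8	0.7	0.6	0.5
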