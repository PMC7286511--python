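experiment	tank	day	slot	n_female	n_male
1a	T1	1	0	0	0
1a	T1	1	1	0	1
1a	T1	1	2	0	1
1a	T1	1	3	1	0
1a	T1	1	4	0	1
1a	T1	1	5	1	0
1a	T1	1	6	1	0
1a	T1	2	0	0	0
1a	T1	2	1	1	1
1a	T1	2	2	1	0
1a	T1	2	3	0	1
1a	T1	2	4	1	0
1a	T1	2	5	0	1
1a	T1	2	6	0	0
1a	T1	3	0	0	0
1a	T1	3	1	1	0
1a	T1	3	2	1	0
1a	T1	3	3	0	1
1a	T1	3	4	0	1
1a	T1	3	5	0	1
1a	T1	3	6	1	0
1a	T1	4	0	0	0
1a	T1	4	1	1	0
1a	T1	4	2	1	1
1a	T1	4	3	0	1
1a	T1	4	4	0	0
1a	T1	4	5	0	1
1a	T1	4	6	1	0
1a	T1	5	0	0	0
1a	T1	5	1	0	1
1a	T1	5	2	0	1
1a	T1	5	3	1	0
1a	T1	5	4	1	0
1a	T1	5	5	0	1
1a	T1	5	6	1	0
1a	T1	6	0	0	0
1a	T1	6	1	1	0
1a	T1	6	2	0	1
1a	T1	6	3	0	1
1a	T1	6	4	0	1
1a	T1	6	5	0	0
1a	T1	6	6	2	0
1b	T3	1	0	1	0
1b	T3	1	1	1	1
1b	T3	1	2	0	0
1b	T3	1	3	1	0
1b	T3	1	4	0	0
1b	T3	1	5	0	1
1b	T3	1	6	0	1
1b	T3	2	0	0	0
1b	T3	2	1	0	0
1b	T3	2	2	1	0
1b	T3	2	3	0	1
1b	T3	2	4	1	0
1b	T3	2	5	1	1
1b	T3	2	6	0	1
1b	T3	3	0	0	0
1b	T3	3	1	0	0
1b	T3	3	2	0	1
1b	T3	3	3	0	1
1b	T3	3	4	1	0
1b	T3	3	5	1	1
1b	T3	3	6	1	0
1b	T3	4	0	0	0
1b	T3	4	1	0	1
1b	T3	4	2	1	1
1b	T3	4	3	0	0
1b	T3	4	4	0	0
1b	T3	4	5	0	1
1b	T3	4	6	2	0
1b	T3	5	0	0	0
1b	T3	5	1	0	1
1b	T3	5	2	1	0
1b	T3	5	3	1	1
1b	T3	5	4	0	0
1b	T3	5	5	0	0
1b	T3	5	6	1	1
2a	T2	1	0	1	0
2a	T2	1	1	1	1
2a	T2	1	2	1	2
2a	T2	2	0	0	0
2a	T2	2	1	1	1
2a	T2	2	2	2	2
2a	T2	3	0	1	0
2a	T2	3	1	1	1
2a	T2	3	2	1	2
2a	T2	4	0	1	0
2a	T2	4	1	1	2
2a	T2	4	2	1	1
2a	T2	5	0	1	0
2a	T2	5	1	0	2
2a	T2	5	2	2	1
2a	T2	6	0	1	1
2a	T2	6	1	1	1
2a	T2	6	2	1	1
2a	T2	7	0	0	0
2a	T2	7	1	1	1
2a	T2	7	2	2	2
2b	T4	1	0	1	0
2b	T4	1	1	1	0
2b	T4	1	2	2	2
2b	T4	2	0	1	0
2b	T4	2	1	1	1
2b	T4	2	2	2	1
2b	T4	3	0	1	0
2b	T4	3	1	2	1
2b	T4	3	2	1	1
2b	T4	4	0	1	0
2b	T4	4	1	1	1
2b	T4	4	2	2	1
2b	T4	5	0	1	0
2b	T4	5	1	1	1
2b	T4	5	2	2	1
2b	T4	6	0	0	1
2b	T4	6	1	2	1
2b	T4	6	2	2	0
2b	T4	7	0	0	1
2b	T4	7	1	2	0
2b	T4	7	2	2	1
3a	T3	1	0	0	0
3a	T3	1	1	1	0
3a	T3	1	2	0	0
3a	T3	1	3	2	0
3a	T3	1	4	1	0
3a	T3	1	5	2	0
3a	T3	1	6	0	0
3a	T3	2	0	0	0
3a	T3	2	1	2	0
3a	T3	2	2	2	0
3a	T3	2	3	1	0
3a	T3	2	4	1	0
3a	T3	2	5	0	0
3a	T3	2	6	0	0
3a	T3	3	0	0	0
3a	T3	3	1	2	0
3a	T3	3	2	1	0
3a	T3	3	3	1	0
3a	T3	3	4	0	0
3a	T3	3	5	1	0
3a	T3	3	6	1	0
3a	T3	4	0	0	0
3a	T3	4	1	2	0
3a	T3	4	2	1	0
3a	T3	4	3	0	0
3a	T3	4	4	0	0
3a	T3	4	5	2	0
3a	T3	4	6	1	0
3a	T3	5	0	0	0
3a	T3	5	1	1	0
3a	T3	5	2	2	0
3a	T3	5	3	0	0
3a	T3	5	4	1	0
3a	T3	5	5	1	0
3a	T3	5	6	1	0
3b	T4	6	0	0	0
3b	T4	6	1	0	0
3b	T4	6	2	0	0
3b	T4	6	3	2	0
3b	T4	6	4	1	0
3b	T4	6	5	1	0
3b	T4	6	6	2	0
3b	T4	7	0	0	0
3b	T4	7	1	0	0
3b	T4	7	2	2	0
3b	T4	7	3	1	0
3b	T4	7	4	1	0
3b	T4	7	5	1	0
3b	T4	7	6	1	0
3b	T4	8	0	0	0
3b	T4	8	1	1	0
3b	T4	8	2	1	0
3b	T4	8	3	1	0
3b	T4	8	4	1	0
3b	T4	8	5	1	0
3b	T4	8	6	1	0
3b	T4	9	0	0	0
3b	T4	9	1	1	0
3b	T4	9	2	1	0
3b	T4	9	3	1	0
3b	T4	9	4	1	0
3b	T4	9	5	1	0
3b	T4	9	6	1	0
3b	T4	10	0	0	0
3b	T4	10	1	1	0
3b	T4	10	2	3	0
3b	T4	10	3	0	0
3b	T4	10	4	0	0
3b	T4	10	5	2	0
3b	T4	10	6	0	0
4a	T1	1	0	0	0
4a	T1	1	1	0	1
4a	T1	1	2	0	1
4a	T1	1	3	0	1
4a	T1	1	4	0	1
4a	T1	1	5	0	1
4a	T1	2	0	0	0
4a	T1	2	1	0	1
4a	T1	2	2	0	1
4a	T1	2	3	0	2
4a	T1	2	4	0	0
4a	T1	2	5	0	1
4a	T1	3	0	0	0
4a	T1	3	1	0	1
4a	T1	3	2	0	1
4a	T1	3	3	0	0
4a	T1	3	4	0	2
4a	T1	3	5	0	1
4a	T1	4	0	0	0
4a	T1	4	1	0	1
4a	T1	4	2	0	1
4a	T1	4	3	0	1
4a	T1	4	4	0	1
4a	T1	4	5	0	1
4a	T1	5	0	0	0
4a	T1	5	1	0	1
4a	T1	5	2	0	1
4a	T1	5	3	0	1
4a	T1	5	4	0	1
4a	T1	5	5	0	1
4b	T2	6	0	0	0
4b	T2	6	1	0	1
4b	T2	6	2	0	1
4b	T2	6	3	0	1
4b	T2	6	4	0	1
4b	T2	6	5	0	1
4b	T2	6	6	0	1
4b	T2	7	0	0	0
4b	T2	7	1	0	2
4b	T2	7	2	0	0
4b	T2	7	3	0	1
4b	T2	7	4	0	1
4b	T2	7	5	0	1
4b	T2	7	6	0	1
4b	T2	8	0	0	0
4b	T2	8	1	0	1
4b	T2	8	2	0	1
4b	T2	8	3	0	1
4b	T2	8	4	0	1
4b	T2	8	5	0	1
4b	T2	8	6	0	1
4b	T2	9	0	0	0
4b	T2	9	1	0	1
4b	T2	9	2	0	1
4b	T2	9	3	0	1
4b	T2	9	4	0	1
4b	T2	9	5	0	1
4b	T2	9	6	0	1
4b	T2	10	0	0	0
4b	T2	10	1	0	1
4b	T2	10	2	0	1
4b	T2	10	3	0	1
4b	T2	10	4	0	1
4b	T2	10	5	0	1
4b	T2	10	6	0	1
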