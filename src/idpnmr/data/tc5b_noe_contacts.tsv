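# Assigned NOE contacts of 6 M urea-denatured TC5b (all-trans Pro isomer),
# transcribed from the published main-chain connectivity table, the side-chain
# contact table around Trp 6, and the accompanying running text. Sequential
# HN-HN marks at proline positions are omitted (prolines carry no backbone HN);
# the i,i+1 entry at Pro 12 is transcribed as an HA(12)-HN(13) contact.
# Peak ids for the Trp 6 side-chain network follow the published numbering;
# main-chain contacts have no peak id (".").
# columns: res_i	atom_i	res_j	atom_j	peak_id	mixing_time_ms
1	HN	2	HN	.	150
2	HN	3	HN	.	150
3	HN	4	HN	.	150
4	HN	5	HN	.	150
5	HN	6	HN	.	150
6	HN	7	HN	.	150
7	HN	8	HN	.	150
8	HN	9	HN	.	150
13	HN	14	HN	.	150
12	HA	13	HN	.	150
4	HA	6	HN	.	150
5	HA	7	HN	.	150
14	HA	16	HN	.	150
4	HA	7	HN	.	150
5	HA	8	HN	.	150
1	HB	3	HN	.	150
4	HG2	6	HN	.	150
5	HB	7	HN	.	150
6	HB	8	HN	.	150
7	HB	9	HN	.	150
12	HD2	14	HN	.	150
6	HB	5	HB	.	400
6	HB	7	HB	.	400
6	HB	18	HD3	.	400
6	HB	19	HD2	.	400
6	HD1	4	HG2	11	400
6	HD1	7	HD2	12	400
6	HD1	16	HG	13	400
6	HE1	4	HD1	5	400
6	HE1	4	HG2	1	400
6	HE1	4	HG2	4	400
6	HE1	7	HB	6	400
6	HE1	7	HD2	5	400
6	HE1	7	HG	7	400
6	HE1	16	HD	3	400
6	HE1	16	HG	2	400
6	HH2	4	HD1	9	400
6	HH2	7	HD2	9	400
6	HH2	16	HG	10	400
6	HZ2	4	HD1	14	400
6	HZ2	7	HD2	14	400
6	HZ2	12	HD2	8	400
6	HZ2	12	HD3	8	400
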