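# reference WC pair conformer in helix frame (z = helix axis)
# strand	atom	x	y	z
s1	P	9.257039	0.623343	-6.634231
s1	OP1	10.586725	0.094089	-6.259590
s1	OP2	9.329096	1.262677	-8.108009
s1	O5'	8.812183	1.754550	-5.578708
s1	C5'	7.866038	2.591253	-6.245275
s1	C4'	6.594747	2.697223	-5.401076
s1	O4'	5.802143	1.493221	-5.513872
s1	C3'	6.944171	2.762351	-3.892429
s1	O3'	7.211267	4.107308	-3.488046
s1	C2'	5.646065	2.235360	-3.235969
s1	C1'	4.947568	1.446823	-4.359990
s1	N9	4.745879	0.057712	-3.944227
s1	C8	5.688108	-0.928459	-3.943448
s1	N7	5.164414	-2.039498	-3.512707
s1	C5	3.859001	-1.832799	-3.212386
s1	C6	2.819842	-2.654743	-2.716932
s1	O6	3.020039	-3.830508	-2.465751
s1	N1	1.602802	-2.102072	-2.522630
s1	C2	1.388742	-0.788528	-2.812357
s1	N2	0.140150	-0.256748	-2.612214
s1	N3	2.345317	-0.014903	-3.274251
s1	C4	3.578762	-0.488423	-3.484458
s2	P	-6.700056	-4.568453	0.347873
s2	OP1	-6.354709	-4.316382	-1.068713
s2	OP2	-8.243241	-5.010852	0.454095
s2	O5'	-6.465386	-3.224825	1.204519
s2	C5'	-7.421977	-2.270537	0.743892
s2	C4'	-6.743187	-1.289175	-0.213847
s2	O4'	-5.320008	-1.236954	0.030180
s2	C3'	-6.842702	-1.793989	-1.675220
s2	O3'	-8.072460	-1.380644	-2.275131
s2	C2'	-5.638651	-1.090889	-2.344652
s2	C1'	-4.708794	-0.733412	-1.168574
s2	N1	-3.398688	-1.359285	-1.361246
s2	C2	-2.371622	-0.629634	-1.830463
s2	O2	-2.543281	0.549744	-2.091914
s2	N3	-1.169822	-1.173530	-2.015493
s2	C4	-0.955492	-2.452736	-1.740533
s2	N4	0.289616	-3.004243	-1.935981
s2	C5	-2.013068	-3.245754	-1.250878
s2	C6	-3.227143	-2.677726	-1.063860
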