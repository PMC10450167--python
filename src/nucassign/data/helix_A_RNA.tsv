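# reference WC pair conformer in helix frame (z = helix axis)
# strand	atom	x	y	z
s1	P	-7.040961	4.752916	-11.319225
s1	OP1	-7.493457	4.938098	-9.923797
s1	OP2	-8.202051	5.230239	-12.326996
s1	O5'	-6.713265	3.198227	-11.575868
s1	C5'	-5.456898	2.931511	-10.952246
s1	C4'	-5.653034	2.796647	-9.441976
s1	O4'	-4.960494	3.857292	-8.748444
s1	C3'	-7.138620	2.985802	-9.069365
s1	O3'	-7.779950	1.719259	-8.903928
s1	C2'	-7.096260	3.751862	-7.726752
s1	O2'	-7.710965	2.982344	-6.691601
s1	C1'	-5.588345	3.936227	-7.451192
s1	N9	-5.337180	5.243861	-6.840908
s1	C8	-6.028302	6.394204	-7.087958
s1	N7	-5.538555	7.365400	-6.373569
s1	C5	-4.507406	6.897309	-5.628062
s1	C6	-3.623599	7.483041	-4.691995
s1	O6	-3.708511	8.665922	-4.408724
s1	N1	-2.687773	6.698015	-4.115550
s1	C2	-2.598459	5.379299	-4.445259
s1	N2	-1.633000	4.607635	-3.848606
s1	N3	-3.413072	4.823170	-5.313033
s1	C4	-4.368917	5.536266	-5.919399
s2	P	3.763188	4.913622	3.280360
s2	OP1	3.958627	5.104193	1.826731
s2	OP2	5.032482	5.503669	4.075761
s2	O5'	3.612915	3.343011	3.600421
s2	C5'	2.554358	2.853159	2.777497
s2	C4'	2.917185	3.051921	1.305322
s2	O4'	1.754287	3.460073	0.551766
s2	C3'	3.919768	4.215929	1.146382
s2	O3'	5.254082	3.715937	1.036695
s2	C2'	3.488443	4.907068	-0.168228
s2	O2'	4.545335	4.858684	-1.128473
s2	C1'	2.274972	4.079173	-0.644478
s2	N1	1.266117	4.954042	-1.246921
s2	C2	0.398856	4.454920	-2.144256
s2	O2	0.461278	3.275017	-2.448128
s2	N3	-0.528736	5.227378	-2.708341
s2	C4	-0.618636	6.513503	-2.396797
s2	N4	-1.579398	7.302156	-2.985098
s2	C5	0.279620	7.068587	-1.462535
s2	C6	1.211909	6.268794	-0.893680
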