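# spacing 1.0
# cutoff 0.9366079042
# anchor : C2' -2.002705 0.637284 1.299302
# anchor : C1' -1.464731 -0.000000 -0.000000
# anchor : O4' -1.968042 0.838150 -1.061825
# x y z
0.000 -5.000 -2.000
0.000 -5.000 -1.000
0.000 -5.000 0.000
0.000 -5.000 1.000
0.000 -5.000 2.000
0.000 -4.000 -4.000
0.000 -4.000 -3.000
0.000 -4.000 -2.000
0.000 -4.000 -1.000
0.000 -4.000 1.000
0.000 -4.000 2.000
0.000 -4.000 3.000
0.000 -4.000 4.000
0.000 -3.000 -4.000
0.000 -3.000 -3.000
0.000 -3.000 0.000
0.000 -3.000 3.000
0.000 -3.000 4.000
0.000 -2.000 -5.000
0.000 -2.000 -4.000
0.000 -2.000 -2.000
0.000 -2.000 -1.000
0.000 -2.000 0.000
0.000 -2.000 1.000
0.000 -2.000 2.000
0.000 -2.000 4.000
0.000 -2.000 5.000
0.000 -1.000 -5.000
0.000 -1.000 -4.000
0.000 -1.000 -2.000
0.000 -1.000 -1.000
0.000 -1.000 0.000
0.000 -1.000 1.000
0.000 -1.000 2.000
0.000 -1.000 4.000
0.000 -1.000 5.000
0.000 0.000 -5.000
0.000 0.000 -3.000
0.000 0.000 -2.000
0.000 0.000 -1.000
0.000 0.000 0.000
0.000 0.000 1.000
0.000 0.000 2.000
0.000 0.000 3.000
0.000 0.000 5.000
0.000 1.000 -5.000
0.000 1.000 -4.000
0.000 1.000 -2.000
0.000 1.000 -1.000
0.000 1.000 0.000
0.000 1.000 1.000
0.000 1.000 2.000
0.000 1.000 4.000
0.000 1.000 5.000
0.000 2.000 -5.000
0.000 2.000 -4.000
0.000 2.000 -2.000
0.000 2.000 -1.000
0.000 2.000 0.000
0.000 2.000 1.000
0.000 2.000 2.000
0.000 2.000 4.000
0.000 2.000 5.000
0.000 3.000 -4.000
0.000 3.000 -3.000
0.000 3.000 0.000
0.000 3.000 3.000
0.000 3.000 4.000
0.000 4.000 -4.000
0.000 4.000 -3.000
0.000 4.000 -2.000
0.000 4.000 -1.000
0.000 4.000 1.000
0.000 4.000 2.000
0.000 4.000 3.000
0.000 4.000 4.000
0.000 5.000 -2.000
0.000 5.000 -1.000
0.000 5.000 0.000
0.000 5.000 1.000
0.000 5.000 2.000
1.000 -5.000 -2.000
1.000 -5.000 -1.000
1.000 -5.000 0.000
1.000 -5.000 1.000
1.000 -5.000 2.000
1.000 -4.000 -3.000
1.000 -4.000 -2.000
1.000 -4.000 -1.000
1.000 -4.000 0.000
1.000 -4.000 1.000
1.000 -4.000 2.000
1.000 -4.000 3.000
1.000 -3.000 -4.000
1.000 -3.000 -3.000
1.000 -3.000 -2.000
1.000 -3.000 -1.000
1.000 -3.000 0.000
1.000 -3.000 1.000
1.000 -3.000 2.000
1.000 -3.000 3.000
1.000 -3.000 4.000
1.000 -2.000 -5.000
1.000 -2.000 -4.000
1.000 -2.000 -3.000
1.000 -2.000 -2.000
1.000 -2.000 -1.000
1.000 -2.000 0.000
1.000 -2.000 1.000
1.000 -2.000 2.000
1.000 -2.000 3.000
1.000 -2.000 4.000
1.000 -2.000 5.000
1.000 -1.000 -5.000
1.000 -1.000 -4.000
1.000 -1.000 -3.000
1.000 -1.000 -2.000
1.000 -1.000 -1.000
1.000 -1.000 0.000
1.000 -1.000 1.000
1.000 -1.000 2.000
1.000 -1.000 3.000
1.000 -1.000 4.000
1.000 -1.000 5.000
1.000 0.000 -5.000
1.000 0.000 -4.000
1.000 0.000 -3.000
1.000 0.000 -2.000
1.000 0.000 -1.000
1.000 0.000 1.000
1.000 0.000 2.000
1.000 0.000 3.000
1.000 0.000 4.000
1.000 0.000 5.000
1.000 1.000 -5.000
1.000 1.000 -4.000
1.000 1.000 -3.000
1.000 1.000 -2.000
1.000 1.000 -1.000
1.000 1.000 0.000
1.000 1.000 1.000
1.000 1.000 2.000
1.000 1.000 3.000
1.000 1.000 4.000
1.000 1.000 5.000
1.000 2.000 -5.000
1.000 2.000 -4.000
1.000 2.000 -3.000
1.000 2.000 -2.000
1.000 2.000 -1.000
1.000 2.000 0.000
1.000 2.000 1.000
1.000 2.000 2.000
1.000 2.000 3.000
1.000 2.000 4.000
1.000 2.000 5.000
1.000 3.000 -4.000
1.000 3.000 -3.000
1.000 3.000 -2.000
1.000 3.000 -1.000
1.000 3.000 0.000
1.000 3.000 1.000
1.000 3.000 2.000
1.000 3.000 3.000
1.000 3.000 4.000
1.000 4.000 -3.000
1.000 4.000 -2.000
1.000 4.000 -1.000
1.000 4.000 0.000
1.000 4.000 1.000
1.000 4.000 2.000
1.000 4.000 3.000
1.000 5.000 -2.000
1.000 5.000 -1.000
1.000 5.000 0.000
1.000 5.000 1.000
1.000 5.000 2.000
2.000 -6.000 -1.000
2.000 -6.000 0.000
2.000 -6.000 1.000
2.000 -5.000 -3.000
2.000 -5.000 -2.000
2.000 -5.000 -1.000
2.000 -5.000 0.000
2.000 -5.000 1.000
2.000 -5.000 2.000
2.000 -5.000 3.000
2.000 -4.000 -4.000
2.000 -4.000 -3.000
2.000 -4.000 -2.000
2.000 -4.000 -1.000
2.000 -4.000 0.000
2.000 -4.000 1.000
2.000 -4.000 2.000
2.000 -4.000 3.000
2.000 -4.000 4.000
2.000 -3.000 -5.000
2.000 -3.000 -4.000
2.000 -3.000 -3.000
2.000 -3.000 -2.000
2.000 -3.000 -1.000
2.000 -3.000 0.000
2.000 -3.000 1.000
2.000 -3.000 2.000
2.000 -3.000 3.000
2.000 -3.000 4.000
2.000 -3.000 5.000
2.000 -2.000 -5.000
2.000 -2.000 -4.000
2.000 -2.000 -3.000
2.000 -2.000 -2.000
2.000 -2.000 2.000
2.000 -2.000 3.000
2.000 -2.000 4.000
2.000 -2.000 5.000
2.000 -1.000 -6.000
2.000 -1.000 -5.000
2.000 -1.000 -4.000
2.000 -1.000 -3.000
2.000 -1.000 -1.000
2.000 -1.000 0.000
2.000 -1.000 1.000
2.000 -1.000 3.000
2.000 -1.000 4.000
2.000 -1.000 5.000
2.000 -1.000 6.000
2.000 0.000 -6.000
2.000 0.000 -5.000
2.000 0.000 -4.000
2.000 0.000 -3.000
2.000 0.000 -1.000
2.000 0.000 0.000
2.000 0.000 1.000
2.000 0.000 3.000
2.000 0.000 4.000
2.000 0.000 5.000
2.000 0.000 6.000
2.000 1.000 -6.000
2.000 1.000 -5.000
2.000 1.000 -4.000
2.000 1.000 -3.000
2.000 1.000 -1.000
2.000 1.000 0.000
2.000 1.000 1.000
2.000 1.000 3.000
2.000 1.000 4.000
2.000 1.000 5.000
2.000 1.000 6.000
2.000 2.000 -5.000
2.000 2.000 -4.000
2.000 2.000 -3.000
2.000 2.000 -2.000
2.000 2.000 2.000
2.000 2.000 3.000
2.000 2.000 4.000
2.000 2.000 5.000
2.000 3.000 -5.000
2.000 3.000 -4.000
2.000 3.000 -3.000
2.000 3.000 -2.000
2.000 3.000 -1.000
2.000 3.000 0.000
2.000 3.000 1.000
2.000 3.000 2.000
2.000 3.000 3.000
2.000 3.000 4.000
2.000 3.000 5.000
2.000 4.000 -4.000
2.000 4.000 -3.000
2.000 4.000 -2.000
2.000 4.000 -1.000
2.000 4.000 0.000
2.000 4.000 1.000
2.000 4.000 2.000
2.000 4.000 3.000
2.000 4.000 4.000
2.000 5.000 -3.000
2.000 5.000 -2.000
2.000 5.000 -1.000
2.000 5.000 0.000
2.000 5.000 1.000
2.000 5.000 2.000
2.000 5.000 3.000
2.000 6.000 -1.000
2.000 6.000 0.000
2.000 6.000 1.000
3.000 -4.000 -1.000
3.000 -4.000 0.000
3.000 -4.000 1.000
3.000 -3.000 -3.000
3.000 -3.000 -2.000
3.000 -3.000 -1.000
3.000 -3.000 0.000
3.000 -3.000 1.000
3.000 -3.000 2.000
3.000 -2.000 -3.000
3.000 -2.000 -2.000
3.000 -2.000 -1.000
3.000 -2.000 0.000
3.000 -2.000 1.000
3.000 -2.000 2.000
3.000 -2.000 3.000
3.000 -1.000 -4.000
3.000 -1.000 -3.000
3.000 -1.000 -2.000
3.000 -1.000 -1.000
3.000 -1.000 0.000
3.000 -1.000 1.000
3.000 -1.000 2.000
3.000 -1.000 3.000
3.000 -1.000 4.000
3.000 0.000 -4.000
3.000 0.000 -3.000
3.000 0.000 -2.000
3.000 0.000 -1.000
3.000 0.000 1.000
3.000 0.000 2.000
3.000 0.000 3.000
3.000 0.000 4.000
3.000 1.000 -4.000
3.000 1.000 -3.000
3.000 1.000 -2.000
3.000 1.000 -1.000
3.000 1.000 0.000
3.000 1.000 1.000
3.000 1.000 2.000
3.000 1.000 3.000
3.000 1.000 4.000
3.000 2.000 -3.000
3.000 2.000 -2.000
3.000 2.000 -1.000
3.000 2.000 0.000
3.000 2.000 1.000
3.000 2.000 2.000
3.000 2.000 3.000
3.000 3.000 -2.000
3.000 3.000 -1.000
3.000 3.000 0.000
3.000 3.000 1.000
3.000 3.000 2.000
3.000 4.000 -1.000
3.000 4.000 0.000
3.000 4.000 1.000
4.000 -4.000 -1.000
4.000 -4.000 0.000
4.000 -4.000 1.000
4.000 -3.000 -3.000
4.000 -3.000 -2.000
4.000 -3.000 -1.000
4.000 -3.000 0.000
4.000 -3.000 1.000
4.000 -3.000 2.000
4.000 -3.000 3.000
4.000 -2.000 -3.000
4.000 -2.000 -2.000
4.000 -2.000 0.000
4.000 -2.000 2.000
4.000 -2.000 3.000
4.000 -1.000 -4.000
4.000 -1.000 -3.000
4.000 -1.000 -1.000
4.000 -1.000 0.000
4.000 -1.000 1.000
4.000 -1.000 3.000
4.000 -1.000 4.000
4.000 0.000 -4.000
4.000 0.000 -3.000
4.000 0.000 -2.000
4.000 0.000 -1.000
4.000 0.000 1.000
4.000 0.000 2.000
4.000 0.000 3.000
4.000 0.000 4.000
4.000 1.000 -4.000
4.000 1.000 -3.000
4.000 1.000 -1.000
4.000 1.000 0.000
4.000 1.000 1.000
4.000 1.000 3.000
4.000 1.000 4.000
4.000 2.000 -3.000
4.000 2.000 -2.000
4.000 2.000 0.000
4.000 2.000 2.000
4.000 2.000 3.000
4.000 3.000 -3.000
4.000 3.000 -2.000
4.000 3.000 -1.000
4.000 3.000 0.000
4.000 3.000 1.000
4.000 3.000 2.000
4.000 3.000 3.000
4.000 4.000 -1.000
4.000 4.000 0.000
4.000 4.000 1.000
5.000 -1.000 -1.000
5.000 -1.000 0.000
5.000 -1.000 1.000
5.000 0.000 -1.000
5.000 0.000 1.000
5.000 1.000 -1.000
5.000 1.000 0.000
5.000 1.000 1.000
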