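value,count
-0.24,2
-0.20,5
-0.16,6
-0.12,44
-0.08,249
-0.04,3336
0.00,15954
0.04,4507
0.08,335
0.12,50
0.16,8
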