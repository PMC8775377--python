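id,occupation,active_time
1,Retired,5.10
2,House keeper,9.69
3,Office worker,2.80
4,Student,0.51
5,House keeper,5.61
6,House keeper,14.78
7,Factory worker,9.93
8,Factory worker,9.42
9,Factory worker,8.72
10,Student,1.53
11,Student,0.76
12,Professional,6.63
13,House keeper,7.65
14,Office worker,6.12
15,Retired,8.16
16,Retired,7.14
17,Office worker,3.57
18,Professional,5.81
19,Office worker,5.61
20,Professional,8.16
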