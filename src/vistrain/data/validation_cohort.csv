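subject,sen,spe,printed_ppv,printed_npv,printed_hr,printed_rhr,printed_ratz
01,.933,.988,.933,.988,.980,.745,.922
02,1,1,1,1,1,.745,1
03,.933,1,1,.988,.990,.752,1
04,1,1,1,1,1,.745,1
05,1,.988,.938,1,.990,.738,1
06,1,1,1,1,1,.745,1
07,1,1,1,1,1,.745,1
08,1,.988,.938,1,.990,.738,1
09,1,1,1,1,1,.745,1
10,1,.976,.882,1,.980,.731,1
11,1,1,1,1,1,.745,1
12,1,1,1,1,1,.745,1
13,1,1,1,1,1,.745,1
14,1,.988,.938,1,.990,.738,1
15,1,.988,.938,1,.990,.738,1
16,1,.976,.882,1,.980,.731,1
17,.933,.988,.933,.988,.980,.745,.922
18,1,1,1,1,1,.745,1
19,.933,.988,.933,.988,.980,.745,.922
20,1,.988,.938,1,.990,.738,1
21,1,.988,.938,1,.990,.738,1
22,.933,1,1,.988,.990,.752,1
23,1,1,1,1,1,.745,1
24,1,1,1,1,1,.745,1
25,1,.988,.938,1,.990,.738,1
26,1,1,1,1,1,.745,1
27,.933,1,1,.988,.990,.752,1
28,1,1,1,1,1,.745,1
29,.867,.988,.929,.977,.970,.752,.916
30,1,1,1,1,1,.745,1
31,1,1,1,1,1,.745,1
32,.933,.988,.933,.988,.980,.745,.922
33,1,1,1,1,1,.745,1
34,1,1,1,1,1,.745,1
35,1,1,1,1,1,.745,1
36,.867,.906,.619,.975,.900,.703,.831
37,1,1,1,1,1,.745,1
38,1,.988,.938,1,.990,.738,1
39,1,1,1,1,1,.745,1
40,.933,.965,.824,.988,.960,.731,.920
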