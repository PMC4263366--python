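index,code,anomer,series,base_name
1,22222,beta,d,glucose
2,24222,beta,d,mannose
3,22242,beta,d,galactose
4,24242,beta,d,talose
5,42222,alpha,d,glucose
6,44222,alpha,d,mannose
7,42242,alpha,d,galactose
8,44242,alpha,d,talose
9,22422,beta,d,allose
10,24422,beta,d,altrose
11,22442,beta,d,gulose
12,24442,beta,d,idose
13,42422,alpha,d,allose
14,44422,alpha,d,altrose
15,42442,alpha,d,gulose
16,44442,alpha,d,idose
17,22224,beta,l,glucose
18,24224,beta,l,mannose
19,22244,beta,l,galactose
20,24244,beta,l,talose
21,42224,alpha,l,glucose
22,44224,alpha,l,mannose
23,42244,alpha,l,galactose
24,44244,alpha,l,talose
25,22424,beta,l,allose
26,24424,beta,l,altrose
27,22444,beta,l,gulose
28,24444,beta,l,idose
29,42424,alpha,l,allose
30,44424,alpha,l,altrose
31,42444,alpha,l,gulose
32,44444,alpha,l,idose
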