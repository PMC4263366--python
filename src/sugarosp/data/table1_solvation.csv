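index,code,anomer,series,base_name,dg_vac,dg_vac_err,dg_water,dg_water_err,ddg_solv,ddg_solv_err
1,22222,beta,d,glucose,26.7,0.2,31.7,0.9,5.0,0.9
2,24222,beta,d,mannose,32.4,0.3,37.9,1.0,5.6,1.0
3,22242,beta,d,galactose,33.1,0.3,34.5,1.3,1.5,1.3
4,24242,beta,d,talose,31.8,0.3,40.8,2.5,9.1,2.5
5,42222,alpha,d,glucose,20.5,0.1,34.4,1.0,13.9,1.0
6,44222,alpha,d,mannose,29.3,0.1,33.9,0.5,4.5,0.5
7,42242,alpha,d,galactose,25.3,0.1,36.2,1.2,10.9,1.2
8,44242,alpha,d,talose,30.1,0.1,37.8,0.5,7.7,0.5
9,22422,beta,d,allose,24.8,0.1,26.9,0.4,2.1,0.4
10,24422,beta,d,altrose,29.1,0.2,28.7,0.3,-0.5,0.4
11,22442,beta,d,gulose,25.2,0.2,27.6,0.4,2.4,0.4
12,24442,beta,d,idose,28.2,0.1,32.7,0.3,4.5,0.3
13,42422,alpha,d,allose,26.9,0.1,31.6,0.3,4.7,0.3
14,44422,alpha,d,altrose,29.4,0.1,29.7,0.4,0.3,0.4
15,42442,alpha,d,gulose,24.6,0.2,31.3,0.3,6.7,0.4
16,44442,alpha,d,idose,28.0,0.1,32.6,0.4,4.6,0.4
17,22224,beta,l,glucose,29.1,0.1,30.8,0.2,1.7,0.2
18,24224,beta,l,mannose,23.7,0.1,30.1,0.2,6.4,0.2
19,22244,beta,l,galactose,29.8,0.1,28.0,0.2,-1.7,0.2
20,24244,beta,l,talose,27.0,0.1,30.4,0.3,3.4,0.3
21,42224,alpha,l,glucose,27.5,0.2,31.2,0.2,3.6,0.3
22,44224,alpha,l,mannose,25.6,0.2,27.2,0.3,1.6,0.4
23,42244,alpha,l,galactose,29.0,0.2,27.0,0.2,-2.0,0.3
24,44244,alpha,l,talose,26.1,0.2,27.0,0.4,0.9,0.4
25,22424,beta,l,allose,31.2,0.2,35.2,0.8,4.0,0.8
26,24424,beta,l,altrose,23.6,0.1,34.6,0.9,10.9,0.9
27,22444,beta,l,gulose,29.5,0.1,32.4,0.3,3.0,0.3
28,24444,beta,l,idose,20.2,0.1,33.2,0.8,12.9,0.8
29,42424,alpha,l,allose,33.6,0.2,45.6,1.4,12.1,1.4
30,44424,alpha,l,altrose,33.8,0.4,36.2,1.4,2.4,1.5
31,42444,alpha,l,gulose,30.8,0.3,38.6,0.9,7.8,0.9
32,44444,alpha,l,idose,27.4,0.2,33.5,1.0,6.1,1.0
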