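index,code,anomer,series,base_name,dg_poseA,dg_poseA_err,ddg_bind_poseA,ddg_bind_poseA_err,dg_poseB,dg_poseB_err,ddg_bind_poseB,ddg_bind_poseB_err
1,22222,beta,d,glucose,22.5,1.1,-9.1,1.5,21.7,0.5,-10.0,1.1
2,24222,beta,d,mannose,46.7,2.1,8.7,2.3,40.5,2.1,2.5,2.4
3,22242,beta,d,galactose,29.2,2.2,-5.3,2.6,28.7,1.1,-5.8,1.7
4,24242,beta,d,talose,41.7,2.3,0.8,3.4,39.9,1.2,-1.0,2.8
5,42222,alpha,d,glucose,31.5,2.3,-2.9,2.6,24.9,1.5,-9.5,1.8
6,44222,alpha,d,mannose,35.9,1.3,2.1,1.4,28.9,2.3,-4.9,2.4
7,42242,alpha,d,galactose,33.3,1.9,-2.9,2.3,28.7,1.8,-7.5,2.2
8,44242,alpha,d,talose,34.5,1.4,-3.3,1.5,30.9,2.1,-6.9,2.2
9,22422,beta,d,allose,18.9,0.6,-8.0,0.7,25.7,1.0,-1.1,1.1
10,24422,beta,d,altrose,36.6,1.2,8.0,1.2,27.8,1.6,-0.9,1.7
11,22442,beta,d,gulose,26.6,1.0,-1.0,1.1,26.6,0.5,-1.0,0.7
12,24442,beta,d,idose,40.0,1.0,7.3,1.1,32.5,0.8,-0.2,0.9
13,42422,alpha,d,allose,35.8,1.0,4.2,1.1,30.6,1.9,-1.0,1.9
14,44422,alpha,d,altrose,38.2,1.8,8.6,1.8,35.5,1.9,5.8,1.9
15,42442,alpha,d,gulose,36.0,0.4,4.7,0.5,35.0,1.3,3.7,1.3
16,44442,alpha,d,idose,36.3,1.0,3.7,1.1,32.4,1.9,-0.2,2.0
17,22224,beta,l,glucose,40.1,2.4,9.3,2.4,39.5,2.4,8.7,2.4
18,24224,beta,l,mannose,35.3,0.4,5.2,0.5,29.4,2.7,-0.6,2.7
19,22244,beta,l,galactose,44.3,1.8,16.3,1.9,45.3,2.1,17.3,2.1
20,24244,beta,l,talose,29.9,1.2,-0.5,1.2,38.9,2.2,8.5,2.3
21,42224,alpha,l,glucose,62.0,2.5,30.8,2.5,51.1,2.5,20.0,2.5
22,44224,alpha,l,mannose,39.1,1.8,12.0,1.8,40.4,1.6,13.3,1.7
23,42244,alpha,l,galactose,60.2,2.5,33.2,2.6,50.1,1.2,23.1,1.2
24,44244,alpha,l,talose,22.6,1.8,-4.3,1.9,40.0,1.9,13.0,1.9
25,22424,beta,l,allose,30.6,1.6,-4.6,1.8,52.5,1.5,17.3,1.7
26,24424,beta,l,altrose,24.7,0.7,-9.9,1.1,40.2,2.8,5.7,3.0
27,22444,beta,l,gulose,37.2,0.9,4.7,0.9,36.2,1.7,3.8,1.8
28,24444,beta,l,idose,24.9,0.6,-8.3,1.0,23.1,1.5,-10.1,1.7
29,42424,alpha,l,allose,101.8,2.5,56.2,2.9,47.3,2.0,1.7,2.4
30,44424,alpha,l,altrose,33.8,1.1,-2.4,1.8,52.8,1.7,16.5,2.3
31,42444,alpha,l,gulose,83.1,1.4,44.5,1.7,42.5,1.9,3.9,2.1
32,44444,alpha,l,idose,21.8,1.7,-11.7,2.0,31.7,1.1,-1.9,1.5
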