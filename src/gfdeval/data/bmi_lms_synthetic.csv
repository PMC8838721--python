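# gfdeval-growth-schema v1 (synthetic LMS reference, not a published standard)
sex,age_years,L,M,S
M,2.0,-1.2000,16.400,0.0850
M,2.5,-1.2980,16.295,0.0894
M,3.0,-1.3951,16.234,0.0938
M,3.5,-1.4903,16.206,0.0981
M,4.0,-1.5827,16.209,0.1022
M,4.5,-1.6714,16.245,0.1062
M,5.0,-1.7556,16.312,0.1100
M,5.5,-1.8344,16.411,0.1135
M,6.0,-1.9071,16.539,0.1168
M,6.5,-1.9730,16.696,0.1198
M,7.0,-2.0315,16.878,0.1224
M,7.5,-2.0819,17.084,0.1247
M,8.0,-2.1239,17.311,0.1266
M,8.5,-2.1569,17.554,0.1281
M,9.0,-2.1808,17.811,0.1291
M,9.5,-2.1952,18.078,0.1298
M,10.0,-2.2000,18.351,0.1300
M,10.5,-2.1952,18.627,0.1298
M,11.0,-2.1808,18.902,0.1291
M,11.5,-2.1569,19.174,0.1281
M,12.0,-2.1239,19.440,0.1266
M,12.5,-2.0819,19.639,0.1247
M,13.0,-2.0315,19.841,0.1224
M,13.5,-1.9730,20.045,0.1198
M,14.0,-1.9071,20.253,0.1168
M,14.5,-1.8344,20.463,0.1135
M,15.0,-1.7556,20.675,0.1100
M,15.5,-1.6714,20.890,0.1062
M,16.0,-1.5827,21.108,0.1022
M,16.5,-1.4903,21.327,0.0981
M,17.0,-1.3951,21.549,0.0938
M,17.5,-1.2980,21.774,0.0894
M,18.0,-1.2000,22.000,0.0850
F,2.0,-1.3000,16.200,0.0900
F,2.5,-1.3882,16.131,0.0949
F,3.0,-1.4756,16.101,0.0998
F,3.5,-1.5613,16.098,0.1045
F,4.0,-1.6444,16.123,0.1091
F,4.5,-1.7243,16.175,0.1136
F,5.0,-1.8000,16.254,0.1178
F,5.5,-1.8710,16.359,0.1217
F,6.0,-1.9364,16.491,0.1254
F,6.5,-1.9957,16.647,0.1287
F,7.0,-2.0483,16.825,0.1316
F,7.5,-2.0937,17.023,0.1341
F,8.0,-2.1315,17.239,0.1362
F,8.5,-2.1612,17.469,0.1378
F,9.0,-2.1827,17.710,0.1390
F,9.5,-2.1957,17.959,0.1398
F,10.0,-2.2000,18.213,0.1400
F,10.5,-2.1957,18.468,0.1398
F,11.0,-2.1827,18.722,0.1390
F,11.5,-2.1612,18.972,0.1378
F,12.0,-2.1315,19.215,0.1362
F,12.5,-2.0937,19.397,0.1341
F,13.0,-2.0483,19.581,0.1316
F,13.5,-1.9957,19.766,0.1287
F,14.0,-1.9364,19.953,0.1254
F,14.5,-1.8710,20.141,0.1217
F,15.0,-1.8000,20.331,0.1178
F,15.5,-1.7243,20.522,0.1136
F,16.0,-1.6444,20.715,0.1091
F,16.5,-1.5613,20.909,0.1045
F,17.0,-1.4756,21.105,0.0998
F,17.5,-1.3882,21.302,0.0949
F,18.0,-1.3000,21.500,0.0900
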