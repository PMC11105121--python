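sex,agemos,L,M,S
male,24,-1.7014,16.6501,0.093
male,27,-1.7131,16.4985,0.094
male,30,-1.7258,16.3582,0.0951
male,33,-1.7393,16.2291,0.0963
male,36,-1.7538,16.1113,0.0975
male,39,-1.7692,16.0046,0.0987
male,42,-1.7855,15.9092,0.1
male,45,-1.8027,15.825,0.1014
male,48,-1.8207,15.7521,0.1028
male,51,-1.8395,15.6903,0.1043
male,54,-1.859,15.6398,0.1057
male,57,-1.879,15.6005,0.1073
male,60,-1.8996,15.5724,0.1088
male,63,-1.9206,15.5556,0.1104
male,66,-1.9419,15.55,0.112
male,69,-1.9633,15.555,0.1137
male,72,-1.9847,15.5699,0.1153
male,75,-2.006,15.5947,0.117
male,78,-2.0269,15.6293,0.1186
male,81,-2.0474,15.6735,0.1203
male,84,-2.0673,15.7272,0.122
male,87,-2.0863,15.79,0.1236
male,90,-2.1044,15.8618,0.1252
male,93,-2.1213,15.9423,0.1268
male,96,-2.1369,16.031,0.1283
male,99,-2.1511,16.1277,0.1298
male,102,-2.1636,16.2319,0.1312
male,105,-2.1745,16.3432,0.1326
male,108,-2.1836,16.4612,0.1339
male,111,-2.1907,16.5854,0.1351
male,114,-2.1958,16.7153,0.1362
male,117,-2.199,16.8505,0.1373
male,120,-2.2,16.9903,0.1382
male,123,-2.199,17.1344,0.1391
male,126,-2.1958,17.2821,0.1399
male,129,-2.1907,17.4329,0.1405
male,132,-2.1836,17.5864,0.141
male,135,-2.1745,17.7421,0.1415
male,138,-2.1636,17.8993,0.1418
male,141,-2.1511,18.0576,0.1419
male,144,-2.1369,18.2165,0.142
male,147,-2.1213,18.3756,0.1419
male,150,-2.1044,18.5343,0.1418
male,153,-2.0863,18.6924,0.1415
male,156,-2.0673,18.8492,0.141
male,159,-2.0474,19.0045,0.1405
male,162,-2.0269,19.1578,0.1399
male,165,-2.006,19.3089,0.1391
male,168,-1.9847,19.4573,0.1382
male,171,-1.9633,19.6029,0.1373
male,174,-1.9419,19.7453,0.1362
male,177,-1.9206,19.8843,0.1351
male,180,-1.8996,20.0196,0.1339
male,183,-1.879,20.1512,0.1326
male,186,-1.859,20.2787,0.1312
male,189,-1.8395,20.4022,0.1298
male,192,-1.8207,20.5214,0.1283
male,195,-1.8027,20.6363,0.1268
male,198,-1.7855,20.7468,0.1252
male,201,-1.7692,20.8529,0.1236
male,204,-1.7538,20.9545,0.122
male,207,-1.7393,21.0517,0.1203
male,210,-1.7258,21.1445,0.1186
male,213,-1.7131,21.2329,0.117
male,216,-1.7014,21.3169,0.1153
male,219,-1.6906,21.3967,0.1137
male,222,-1.6806,21.4722,0.112
male,225,-1.6715,21.5437,0.1104
male,228,-1.6632,21.6111,0.1088
male,231,-1.6557,21.6746,0.1073
male,234,-1.6489,21.7344,0.1057
male,237,-1.6428,21.7905,0.1043
male,240,-1.6373,21.8431,0.1028
female,24,-1.7014,16.4001,0.093
female,27,-1.7131,16.2485,0.094
female,30,-1.7258,16.1082,0.0951
female,33,-1.7393,15.9791,0.0963
female,36,-1.7538,15.8613,0.0975
female,39,-1.7692,15.7546,0.0987
female,42,-1.7855,15.6592,0.1
female,45,-1.8027,15.575,0.1014
female,48,-1.8207,15.5021,0.1028
female,51,-1.8395,15.4403,0.1043
female,54,-1.859,15.3898,0.1057
female,57,-1.879,15.3505,0.1073
female,60,-1.8996,15.3224,0.1088
female,63,-1.9206,15.3056,0.1104
female,66,-1.9419,15.3,0.112
female,69,-1.9633,15.305,0.1137
female,72,-1.9847,15.3199,0.1153
female,75,-2.006,15.3447,0.117
female,78,-2.0269,15.3793,0.1186
female,81,-2.0474,15.4235,0.1203
female,84,-2.0673,15.4772,0.122
female,87,-2.0863,15.54,0.1236
female,90,-2.1044,15.6118,0.1252
female,93,-2.1213,15.6923,0.1268
female,96,-2.1369,15.781,0.1283
female,99,-2.1511,15.8777,0.1298
female,102,-2.1636,15.9819,0.1312
female,105,-2.1745,16.0932,0.1326
female,108,-2.1836,16.2112,0.1339
female,111,-2.1907,16.3354,0.1351
female,114,-2.1958,16.4653,0.1362
female,117,-2.199,16.6005,0.1373
female,120,-2.2,16.7403,0.1382
female,123,-2.199,16.8844,0.1391
female,126,-2.1958,17.0321,0.1399
female,129,-2.1907,17.1829,0.1405
female,132,-2.1836,17.3364,0.141
female,135,-2.1745,17.4921,0.1415
female,138,-2.1636,17.6493,0.1418
female,141,-2.1511,17.8076,0.1419
female,144,-2.1369,17.9665,0.142
female,147,-2.1213,18.1256,0.1419
female,150,-2.1044,18.2843,0.1418
female,153,-2.0863,18.4424,0.1415
female,156,-2.0673,18.5992,0.141
female,159,-2.0474,18.7545,0.1405
female,162,-2.0269,18.9078,0.1399
female,165,-2.006,19.0589,0.1391
female,168,-1.9847,19.2073,0.1382
female,171,-1.9633,19.3529,0.1373
female,174,-1.9419,19.4953,0.1362
female,177,-1.9206,19.6343,0.1351
female,180,-1.8996,19.7696,0.1339
female,183,-1.879,19.9012,0.1326
female,186,-1.859,20.0287,0.1312
female,189,-1.8395,20.1522,0.1298
female,192,-1.8207,20.2714,0.1283
female,195,-1.8027,20.3863,0.1268
female,198,-1.7855,20.4968,0.1252
female,201,-1.7692,20.6029,0.1236
female,204,-1.7538,20.7045,0.122
female,207,-1.7393,20.8017,0.1203
female,210,-1.7258,20.8945,0.1186
female,213,-1.7131,20.9829,0.117
female,216,-1.7014,21.0669,0.1153
female,219,-1.6906,21.1467,0.1137
female,222,-1.6806,21.2222,0.112
female,225,-1.6715,21.2937,0.1104
female,228,-1.6632,21.3611,0.1088
female,231,-1.6557,21.4246,0.1073
female,234,-1.6489,21.4844,0.1057
female,237,-1.6428,21.5405,0.1043
female,240,-1.6373,21.5931,0.1028
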