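# Published standardized estimates for the 7-factor hybrid PCL-5 model in a
# sample of 641 conflict-exposed adolescents: loading before distress control
# (lambda_before), loading after regressing each item on the K10 total
# (lambda_after), attenuation z statistic and two-sided p, and the
# standardized distress path (beta_distress). Used as the default generating
# truth of the synthetic-data module and as worked-example inputs.
item,factor,lambda_before,lambda_after,z,p,beta_distress
B1,In,0.515,0.412,2.349,0.019,0.306
B2,In,0.709,0.587,3.788,0.000,0.396
B3,In,0.679,0.609,2.142,0.032,0.315
B4,In,0.694,0.611,2.592,0.010,0.336
B5,In,0.657,0.546,3.123,0.002,0.363
C1,Av,0.708,0.619,2.854,0.004,0.349
C2,Av,0.754,0.643,3.909,0.000,0.387
D1,NA,0.657,0.539,3.300,0.001,0.378
D2,NA,0.643,0.522,3.290,0.001,0.377
D3,NA,0.706,0.567,4.216,0.000,0.419
D4,NA,0.654,0.529,3.456,0.001,0.383
D5,An,0.709,0.587,3.788,0.000,0.396
D6,An,0.696,0.584,3.411,0.000,0.378
D7,An,0.748,0.643,3.664,0.000,0.387
E1,EB,0.715,0.624,2.961,0.003,0.355
E2,EB,0.682,0.569,3.336,0.001,0.373
E3,AA,0.556,0.476,1.951,0.051,0.280
E4,AA,0.773,0.650,2.826,0.004,0.348
E5,DA,0.749,0.612,4.618,0.000,0.439
E6,DA,0.654,0.484,4.260,0.000,0.426
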