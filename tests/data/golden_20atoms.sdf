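golden
     RDKit          3D

 20  0  0  0  0  0  0  0  0  0999 V2000
    1.4067   -2.2854   -1.5244 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.3957    3.9664   -2.8621 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.3702   -2.5534   -1.1228 N   0  0  0  0  0  0  0  0  0  0  0  0
   -2.6430    0.7101    0.9345 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.1569    0.5258   -3.9630 N   0  0  0  0  0  0  0  0  0  0  0  0
   -0.2790    3.8050    2.3954 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7746   -1.3972   -2.3492 N   0  0  0  0  0  0  0  0  0  0  0  0
   -0.4582   -1.7757    2.9997 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.2947   -1.8060    2.4575 N   0  0  0  0  0  0  0  0  0  0  0  0
   -1.8531   -1.8555   -3.4329 O   0  0  0  0  0  0  0  0  0  0  0  0
   -0.2623   -1.8864    3.1115 N   0  0  0  0  0  0  0  0  0  0  0  0
   -1.7095    2.1901   -0.1020 N   0  0  0  0  0  0  0  0  0  0  0  0
   -0.2558    3.7194    3.1858 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.3677   -2.0384   -2.5217 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.2438    0.4307   -1.0267 O   0  0  0  0  0  0  0  0  0  0  0  0
    2.6712   -1.2098    1.4532 S   0  0  0  0  0  0  0  0  0  0  0  0
   -2.1732   -3.8090    1.5690 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3052   -1.2641   -1.7933 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.9893    0.5608   -1.3292 N   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5952   -2.3846    0.0413 N   0  0  0  0  0  0  0  0  0  0  0  0
M  END
>  <PARTIAL_CHARGES>  (1) 
0.303954 -0.034171 -0.009761 0.115044 -0.129040 0.011474 -0.229758 0.224700 -0.257164 -0.113999 -0.162797 -0.232312 0.101660 -0.180047 0.263323 -0.113715 0.436793 0.114477 -0.267232 0.158572

$$$$
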