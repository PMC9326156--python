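@<TRIPOS>MOLECULE
golden
20 0 0 0 0
SMALL
USER_CHARGES
@<TRIPOS>ATOM
      1 C1          1.4067      -2.2854      -1.5244 C     1 MOL   0.303954
      2 C2          2.3957       3.9664      -2.8621 C     1 MOL  -0.034171
      3 N3         -3.3702      -2.5534      -1.1228 N     1 MOL  -0.009761
      4 C4         -2.6430       0.7101       0.9345 C     1 MOL   0.115044
      5 N5         -3.1569       0.5258      -3.9630 N     1 MOL  -0.129040
      6 C6         -0.2790       3.8050       2.3954 C     1 MOL   0.011474
      7 N7          0.7746      -1.3972      -2.3492 N     1 MOL  -0.229758
      8 C8         -0.4582      -1.7757       2.9997 C     1 MOL   0.224700
      9 N9         -2.2947      -1.8060       2.4575 N     1 MOL  -0.257164
     10 O10        -1.8531      -1.8555      -3.4329 O     1 MOL  -0.113999
     11 N11        -0.2623      -1.8864       3.1115 N     1 MOL  -0.162797
     12 N12        -1.7095       2.1901      -0.1020 N     1 MOL  -0.232312
     13 C13        -0.2558       3.7194       3.1858 C     1 MOL   0.101660
     14 H14        -3.3677      -2.0384      -2.5217 H     1 MOL  -0.180047
     15 O15         3.2438       0.4307      -1.0267 O     1 MOL   0.263323
     16 S16         2.6712      -1.2098       1.4532 S     1 MOL  -0.113715
     17 O17        -2.1732      -3.8090       1.5690 O     1 MOL   0.436793
     18 C18        -1.3052      -1.2641      -1.7933 C     1 MOL   0.114477
     19 N19        -1.9893       0.5608      -1.3292 N     1 MOL  -0.267232
     20 N20        -0.5952      -2.3846       0.0413 N     1 MOL   0.158572
@<TRIPOS>BOND
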