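class_id,name,count
0,Stand,1886
1,Sit,1874
2,Talk-sit,1797
3,Talk-stand,1866
4,Stand-sit,2178
5,Lay,1813
6,Lay-stand,1762
7,Pick,1333
8,Jump,666
9,Push-up,480
10,Sit-up,1005
11,Walk,882
12,Walk-backward,317
13,Walk-circle,259
14,Run,595
15,Stair-up,798
16,Stair-down,781
17,Table-tennis,458
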