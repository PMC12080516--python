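endoscopist,sex,height_cm,weight_lb,reba_optimal,reba_low
1,M,185,198,2.58,2.62
2,F,165,140,2.67,4.6
3,M,180,186,3.54,5.27
4,M,193,235,1.68,4.47
5,F,160,140,2.26,9.14
6,F,165,140,2.62,3.87
7,F,168,145,3.15,5.14
8,F,160,128,2.29,3.29
9,M,185,175,1.97,3.55
10,M,167,145,2.72,4.48
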