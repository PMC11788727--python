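group_no,before_total,before_warning,before_rejection,after_total,after_warning,after_rejection,paper_label
1,0,0,0,0,0,0,No
2,0,0,0,1,1,0,Yes
3,3,3,0,3,0,3,Yes
4,1,1,0,0,0,0,Yes
5,0,0,0,0,0,0,No
6,5,3,2,1,1,0,Yes
7,3,2,1,8,1,7,Yes
8,2,1,1,1,0,1,Yes
9,3,2,1,2,2,0,Yes
10,1,1,0,1,1,0,No
11,2,2,0,8,3,5,Yes
12,0,0,0,0,0,0,No
13,1,1,0,1,1,0,No
14,1,1,0,0,0,0,Yes
15,0,0,0,0,0,0,No
16,1,1,0,1,0,1,Yes
17,2,2,0,2,0,2,No
18,1,1,0,7,2,5,Yes
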