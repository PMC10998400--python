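item_id,status
1,selected
2,up_for_discussion
3,not_selected
4,selected
5,selected
6,selected
7,up_for_discussion
8,up_for_discussion
9,up_for_discussion
10,selected
11,up_for_discussion
12.1,selected
12.2,selected
12.3,selected
13,selected
14.1,selected
14.2,up_for_discussion
14.3,selected
14.4,up_for_discussion
14.5,up_for_discussion
15,selected
16,selected
17,selected
18,selected
19,up_for_discussion
20,selected
21.1,selected
21.2,selected
22,selected
23.1,selected
23.2,selected
23.3,selected
23.4,selected
23.5,up_for_discussion
23.6,selected
23.7,up_for_discussion
23.8,up_for_discussion
24.1,up_for_discussion
24.2,selected
25,selected
26,selected
27.1,selected
27.2,up_for_discussion
27.3,selected
27.4,selected
27.5,up_for_discussion
27.6,not_selected
27.7,not_selected
27.8,not_selected
27.9,selected
28,selected
29,selected
30,selected
31,not_selected
32,up_for_discussion
33,not_selected
34,not_selected
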