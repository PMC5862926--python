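Height,Gender,Pitch
64,female,very high
62,female,very high
66,female,very high
65,female,very high
60,female,very high
61,female,very high
65,female,very high
66,female,very high
65,female,very high
63,female,very high
67,female,very high
65,female,very high
62,female,very high
65,female,very high
68,female,very high
65,female,very high
63,female,very high
65,female,very high
62,female,very high
65,female,very high
66,female,very high
62,female,very high
65,female,very high
63,female,very high
65,female,very high
66,female,very high
65,female,very high
62,female,very high
65,female,very high
66,female,very high
65,female,very high
61,female,very high
65,female,very high
66,female,very high
65,female,very high
62,female,very high
63,female,high
67,female,high
60,female,high
67,female,high
66,female,high
62,female,high
65,female,high
62,female,high
61,female,high
62,female,high
66,female,high
60,female,high
65,female,high
65,female,high
61,female,high
64,female,high
68,female,high
64,female,high
63,female,high
62,female,high
64,female,high
62,female,high
64,female,high
65,female,high
60,female,high
65,female,high
70,female,high
63,female,high
67,female,high
66,female,high
65,female,low
62,female,low
68,female,low
67,female,low
67,female,low
63,female,low
67,female,low
66,female,low
63,female,low
72,female,low
62,female,low
61,female,low
66,female,low
64,female,low
60,female,low
61,female,low
66,female,low
66,female,low
66,female,low
62,female,low
70,female,low
65,female,low
64,female,low
63,female,low
65,female,low
69,female,low
61,female,low
66,female,low
65,female,low
61,female,low
63,female,low
64,female,low
67,female,low
66,female,low
68,female,low
70,female,very low
65,female,very low
65,female,very low
65,female,very low
64,female,very low
66,female,very low
64,female,very low
70,female,very low
63,female,very low
70,female,very low
64,female,very low
63,female,very low
67,female,very low
65,female,very low
63,female,very low
66,female,very low
66,female,very low
64,female,very low
64,female,very low
70,female,very low
70,female,very low
66,female,very low
66,female,very low
66,female,very low
69,female,very low
67,female,very low
65,female,very low
69,male,very high
72,male,very high
71,male,very high
66,male,very high
76,male,very high
74,male,very high
71,male,very high
66,male,very high
68,male,very high
67,male,very high
70,male,very high
65,male,very high
72,male,very high
70,male,very high
68,male,very high
64,male,very high
73,male,very high
66,male,very high
68,male,very high
67,male,very high
64,male,very high
68,male,high
73,male,high
69,male,high
71,male,high
69,male,high
76,male,high
71,male,high
69,male,high
71,male,high
66,male,high
69,male,high
71,male,high
71,male,high
71,male,high
69,male,high
70,male,high
69,male,high
68,male,high
70,male,high
68,male,high
69,male,high
72,male,low
70,male,low
72,male,low
69,male,low
73,male,low
71,male,low
72,male,low
68,male,low
68,male,low
71,male,low
66,male,low
68,male,low
71,male,low
73,male,low
73,male,low
70,male,low
68,male,low
70,male,low
75,male,low
68,male,low
71,male,low
70,male,low
74,male,low
70,male,low
75,male,low
75,male,low
69,male,low
72,male,low
71,male,low
70,male,low
71,male,low
68,male,low
70,male,low
75,male,low
72,male,low
66,male,low
72,male,low
70,male,low
69,male,low
72,male,very low
75,male,very low
67,male,very low
75,male,very low
74,male,very low
72,male,very low
72,male,very low
74,male,very low
72,male,very low
72,male,very low
74,male,very low
70,male,very low
66,male,very low
68,male,very low
75,male,very low
68,male,very low
70,male,very low
72,male,very low
67,male,very low
70,male,very low
70,male,very low
69,male,very low
72,male,very low
71,male,very low
74,male,very low
75,male,very low
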