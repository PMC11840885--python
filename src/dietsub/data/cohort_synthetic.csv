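age,bmi,smoker,exercise,pmeat,chicken,fish,dairy,death
70,22.0,1,1.1,2,2,3,3,0
60,22.9,0,3.0,2,5,4,3,0
79,28.2,0,1.0,1,2,2,5,0
61,28.6,1,0.2,0,3,3,0,0
76,27.6,1,6.2,0,3,1,3,0
69,28.6,0,1.6,0,4,0,6,0
78,28.7,0,3.0,2,0,3,3,1
67,26.9,0,3.5,0,4,3,6,0
64,24.0,0,2.7,0,3,1,4,0
78,32.5,1,2.2,2,2,3,4,1
77,28.4,0,6.7,4,4,5,4,0
75,27.9,0,1.1,1,4,2,3,0
66,22.4,0,0.8,1,3,2,4,0
71,28.9,0,0.5,0,3,1,5,0
66,24.1,0,2.1,1,2,2,3,0
64,30.4,1,2.6,1,3,3,5,0
68,28.0,0,5.3,1,5,1,4,0
76,26.4,0,3.5,2,2,3,5,0
74,23.7,0,2.4,1,3,3,4,0
69,26.4,0,2.1,1,4,1,4,0
75,26.3,0,2.2,1,3,3,4,0
65,23.2,0,2.1,1,2,3,0,0
68,26.4,0,1.3,1,4,2,5,0
64,29.6,0,3.5,0,6,1,3,0
77,30.1,0,4.8,1,4,2,1,0
67,30.8,1,1.3,2,2,2,5,0
62,27.7,1,1.6,1,1,1,2,0
68,25.0,0,5.8,1,5,2,1,0
75,25.8,0,3.9,1,4,4,4,0
70,29.7,0,2.4,1,3,4,5,1
66,22.9,1,3.3,2,4,3,2,0
78,24.0,0,4.6,2,2,3,3,1
60,26.9,1,2.3,4,1,0,3,0
62,29.0,0,4.5,0,2,1,2,0
79,26.6,0,5.4,2,4,5,5,0
78,21.7,0,2.4,0,3,4,5,0
73,25.7,0,6.0,3,3,4,2,0
74,26.4,0,2.2,2,2,1,7,1
64,19.5,1,2.6,1,1,1,4,0
77,25.1,0,3.4,0,3,1,4,0
73,19.9,1,2.3,2,2,3,5,0
61,24.8,0,5.0,1,5,2,5,0
60,29.6,0,6.4,0,2,2,3,0
78,28.8,1,5.2,4,4,3,3,0
77,30.9,0,5.5,1,6,2,3,0
60,29.7,1,3.1,3,3,4,4,1
68,30.6,1,7.8,4,4,4,2,0
69,29.6,0,3.1,3,7,5,3,0
64,26.4,0,0.9,0,3,3,3,0
60,24.2,0,6.5,2,3,4,4,0
79,17.4,1,0.7,3,1,0,5,0
79,30.6,0,1.8,0,4,3,3,0
61,31.0,0,5.1,1,5,3,3,0
64,25.0,0,2.3,2,5,1,6,0
78,30.3,0,3.5,0,4,2,5,1
61,27.6,0,4.8,2,4,2,5,0
68,31.2,1,3.6,4,5,2,3,1
66,25.2,0,2.3,2,2,2,3,0
62,24.0,0,0.7,1,3,2,2,0
64,27.1,0,5.1,0,2,3,4,0
65,26.6,1,2.0,3,3,3,2,0
61,20.9,0,2.3,0,2,1,2,0
68,21.7,0,2.6,5,6,3,5,0
60,26.5,0,1.1,4,2,3,4,0
65,27.6,0,2.5,1,1,3,4,0
61,19.6,0,0.7,1,5,2,7,0
76,30.3,0,2.7,1,3,3,4,0
69,29.9,1,0.7,1,1,1,6,0
68,31.0,0,1.6,2,1,2,4,1
63,28.5,1,3.4,4,3,3,5,0
71,28.3,0,0.7,1,2,2,4,0
78,21.3,0,3.6,1,2,6,5,0
78,25.5,0,2.4,2,2,2,1,0
67,22.0,1,0.8,4,3,3,3,1
71,24.3,0,4.4,1,1,3,4,0
75,27.7,1,2.8,3,0,3,2,0
66,34.5,0,2.3,1,2,3,5,0
69,23.3,0,6.5,1,1,4,2,0
78,21.2,1,6.0,2,4,3,4,0
66,24.2,0,1.5,2,2,3,5,0
74,24.3,1,4.0,3,3,3,5,0
73,22.3,0,6.4,0,4,1,3,0
64,27.7,0,0.6,0,2,1,8,0
76,29.6,0,7.3,0,2,1,3,0
74,24.0,0,2.3,2,0,2,2,0
75,25.6,0,2.4,0,1,2,1,1
64,26.9,0,3.7,1,4,2,5,1
76,23.7,1,3.7,2,2,3,3,0
78,27.3,1,5.0,4,5,2,3,0
78,26.6,0,4.6,1,4,1,4,0
62,23.1,0,3.4,2,5,4,3,0
71,24.5,0,3.3,3,0,1,2,0
70,24.5,1,0.7,1,4,2,6,0
78,25.5,1,1.7,1,1,1,4,0
75,29.4,0,0.6,2,6,1,6,0
62,25.3,0,3.3,3,5,2,2,0
79,35.2,0,8.5,1,6,2,4,0
72,28.7,0,5.3,1,4,3,2,0
71,26.7,1,3.3,3,5,6,2,0
73,23.4,0,1.2,2,5,2,4,0
67,26.1,0,0.9,2,1,4,5,0
61,27.8,1,2.9,4,3,2,1,0
62,22.3,1,5.6,5,3,3,7,0
78,26.6,1,6.1,2,3,4,4,0
65,25.5,0,3.2,2,2,1,5,0
61,27.7,0,1.9,1,2,1,4,0
66,30.1,0,2.0,1,4,2,6,0
65,28.1,0,2.2,0,5,5,4,1
65,26.9,1,4.9,0,1,4,5,0
63,32.7,0,4.4,1,2,2,4,0
68,25.0,0,2.6,2,4,3,7,0
78,24.5,0,1.4,1,3,3,4,0
69,22.5,0,2.5,2,4,3,3,0
62,25.8,1,3.0,1,4,3,5,0
65,27.4,0,2.1,1,3,2,6,0
68,27.6,1,2.5,6,4,2,5,0
64,27.0,0,2.8,1,3,4,4,0
71,22.2,0,2.6,4,4,2,4,0
61,25.0,0,4.1,3,3,4,5,0
69,26.5,0,4.5,2,6,2,4,0
74,29.2,0,0.1,1,3,0,2,0
78,27.6,0,6.1,0,4,0,5,0
76,30.8,1,7.6,1,4,2,1,0
63,25.2,0,2.9,2,3,2,2,0
67,23.1,1,2.6,1,2,4,5,0
78,23.1,0,1.1,0,2,2,3,0
78,22.2,0,0.0,1,3,1,5,0
76,22.9,0,2.0,5,4,3,6,0
67,29.9,0,1.8,0,2,2,3,0
76,29.3,0,4.2,2,1,2,4,0
67,21.3,0,2.7,1,4,2,4,0
69,19.1,1,4.4,2,1,0,3,0
64,28.0,0,5.1,1,3,3,1,0
75,27.8,0,0.3,0,3,6,6,0
68,28.7,1,0.0,4,4,4,4,0
68,21.2,0,1.4,0,2,3,4,0
60,28.0,1,0.6,4,3,6,5,0
60,24.7,1,0.9,1,2,1,3,0
60,22.0,0,3.1,2,4,2,6,0
74,27.4,0,1.3,2,5,3,2,1
71,26.2,0,2.9,2,2,2,4,0
73,27.0,1,2.4,3,2,1,2,0
73,28.8,0,6.6,2,4,3,3,0
63,23.4,0,2.3,1,1,3,2,0
60,25.4,1,3.0,3,5,3,2,0
61,27.2,0,0.3,1,3,0,3,0
65,26.7,0,1.3,1,3,2,4,0
71,26.5,0,1.8,1,4,4,8,1
67,26.2,0,3.1,0,3,4,6,0
76,23.4,1,3.9,3,4,3,5,1
60,17.4,1,4.6,2,4,4,3,0
62,23.9,0,4.0,1,4,1,2,0
78,26.2,0,4.5,2,4,3,3,0
76,27.1,0,1.9,2,2,2,1,0
64,24.7,1,3.9,0,4,1,4,0
64,34.3,1,2.0,0,3,5,4,0
64,22.9,0,3.6,1,0,2,2,0
69,22.5,0,1.9,0,3,1,1,0
69,21.9,0,0.5,2,5,0,4,0
67,26.6,0,3.9,0,3,4,2,0
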