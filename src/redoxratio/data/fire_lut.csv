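index,r,g,b
0,0,0,0
1,0,0,7
2,0,0,15
3,0,0,22
4,0,0,30
5,0,0,37
6,0,0,44
7,0,0,52
8,0,0,59
9,0,0,64
10,0,0,69
11,0,0,73
12,0,0,77
13,1,0,81
14,1,0,86
15,1,0,90
16,1,0,94
17,3,0,98
18,6,0,102
19,8,0,107
20,11,0,111
21,14,0,115
22,17,0,119
23,20,0,123
24,23,0,127
25,26,0,131
26,29,0,136
27,32,0,140
28,35,0,144
29,38,0,148
30,41,0,153
31,43,0,157
32,46,0,161
33,49,0,165
34,52,0,169
35,55,0,172
36,58,0,175
37,61,0,178
38,64,0,182
39,67,0,185
40,70,0,188
41,73,0,192
42,76,0,195
43,79,0,198
44,82,0,202
45,85,0,205
46,88,0,209
47,91,0,212
48,94,0,215
49,97,0,219
50,100,0,221
51,103,0,221
52,106,0,222
53,109,0,223
54,112,0,224
55,114,0,225
56,117,0,226
57,120,0,227
58,123,0,226
59,126,0,224
60,129,0,222
61,132,0,220
62,135,0,218
63,138,0,216
64,141,0,214
65,144,0,212
66,146,0,209
67,148,0,206
68,150,0,202
69,152,0,199
70,154,0,195
71,156,0,192
72,158,0,188
73,160,0,185
74,162,0,181
75,163,0,177
76,165,0,174
77,166,0,170
78,167,0,167
79,169,0,163
80,170,0,159
81,171,0,156
82,173,0,152
83,174,0,148
84,175,0,145
85,177,0,141
86,178,0,138
87,179,0,134
88,181,0,131
89,182,0,127
90,183,0,124
91,185,0,120
92,186,0,117
93,187,0,113
94,189,0,110
95,190,0,106
96,191,0,103
97,193,0,99
98,194,0,96
99,195,0,92
100,197,2,88
101,198,4,85
102,200,6,81
103,201,7,78
104,203,9,74
105,204,11,71
106,206,12,67
107,207,14,64
108,208,17,60
109,210,19,57
110,211,22,53
111,212,24,50
112,213,27,46
113,214,29,43
114,216,32,39
115,217,35,36
116,218,37,32
117,220,40,28
118,221,43,25
119,223,45,21
120,224,48,17
121,226,51,14
122,227,53,10
123,228,56,6
124,230,59,5
125,231,61,4
126,232,64,3
127,234,67,3
128,235,69,2
129,237,72,2
130,238,75,1
131,239,77,0
132,241,80,0
133,242,83,0
134,243,85,0
135,245,88,0
136,246,91,0
137,248,93,0
138,249,96,0
139,251,99,0
140,252,101,0
141,252,103,0
142,253,105,0
143,253,107,0
144,254,109,0
145,254,111,0
146,254,113,0
147,255,115,0
148,255,117,0
149,255,119,0
150,255,121,0
151,255,123,0
152,255,125,0
153,255,127,0
154,255,129,0
155,255,130,0
156,255,132,0
157,255,134,0
158,255,136,0
159,255,138,0
160,255,139,0
161,255,141,0
162,255,143,0
163,255,144,0
164,255,146,0
165,255,148,0
166,255,150,0
167,255,151,0
168,255,153,0
169,255,155,0
170,255,156,0
171,255,158,0
172,255,160,0
173,255,161,0
174,255,163,0
175,255,165,0
176,255,167,0
177,255,168,0
178,255,170,0
179,255,172,0
180,255,173,0
181,255,175,0
182,255,177,0
183,255,179,0
184,255,181,0
185,255,182,0
186,255,184,0
187,255,186,0
188,255,188,0
189,255,190,0
190,255,191,0
191,255,193,0
192,255,195,0
193,255,197,0
194,255,199,0
195,255,201,0
196,255,202,0
197,255,204,0
198,255,206,0
199,255,208,0
200,255,209,0
201,255,211,0
202,255,213,0
203,255,214,0
204,255,216,0
205,255,218,0
206,255,220,0
207,255,221,0
208,255,223,0
209,255,225,0
210,255,227,0
211,255,229,0
212,255,231,0
213,255,232,0
214,255,234,1
215,255,236,5
216,255,238,9
217,255,239,13
218,255,241,18
219,255,243,22
220,255,244,26
221,255,246,30
222,255,248,35
223,255,249,42
224,255,250,50
225,255,250,57
226,255,251,65
227,255,252,73
228,255,253,80
229,255,254,88
230,255,255,96
231,255,255,103
232,255,255,111
233,255,255,118
234,255,255,126
235,255,255,133
236,255,255,141
237,255,255,148
238,255,255,156
239,255,255,163
240,255,255,171
241,255,255,179
242,255,255,186
243,255,255,194
244,255,255,202
245,255,255,209
246,255,255,217
247,255,255,224
248,255,255,228
249,255,255,232
250,255,255,236
251,255,255,239
252,255,255,243
253,255,255,247
254,255,255,251
255,255,255,255
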