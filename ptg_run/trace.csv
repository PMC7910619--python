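sweep,log_joint
0,-64.06316368004508
1,-65.20864903992496
2,-56.69884665169183
3,-50.884934294486186
4,-43.84864451734303
5,-49.42502500397201
6,-53.01014447700824
7,-57.165040467326364
8,-56.309296856226226
9,-50.459443709329115
10,-43.90754293453426
11,-51.499715441007936
12,-41.59117850298554
13,-39.35531952514842
14,-34.44621369266078
15,-28.980214932313356
16,-33.021707888085274
17,-25.19900449560746
18,-24.150112553799552
19,-28.195899387040164
20,-31.544281071102763
21,-27.673703537608237
22,-29.75614443778463
23,-34.88947791499189
24,-43.66686401799326
25,-46.67846680682641
26,-38.73055385012415
27,-40.33600483167602
28,-40.06904517152268
29,-40.24388239699928
30,-37.71502968510379
31,-44.4936076508676
32,-45.8218825018927
33,-43.38238197879316
34,-41.39561440105578
35,-40.5541257465738
36,-43.25180560264739
37,-48.03972167181897
38,-47.123006762489936
39,-50.19314352624481
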