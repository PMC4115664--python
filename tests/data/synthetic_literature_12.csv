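study_id,d,n_treat,n_ctrl,subgroup,variance,se,z,p_two_sided,significant,imputed
sim0001,0.37248300601514717,28,30,,0.070243684476671467,0.26503525138492701,1.4054092958153976,0.15989960409862325,False,False
sim0002,0.051056278406987489,12,21,,0.13099187706699872,0.36192799983836388,0.14106750080068162,0.8878166174717268,False,False
sim0003,0.55575388741586773,25,27,,0.080006867646439439,0.2828548526125006,1.9648023793221872,0.049437114721048184,True,False
sim0004,0.68535883312940138,20,18,,0.11173603884698312,0.33426941057623433,2.0503187292786897,0.040333338081183945,True,False
sim0005,0.71462145520827447,37,26,,0.069541611712724161,0.2637074358313094,2.7099025590822157,0.0067302977270636269,True,False
sim0006,0.27107247095367876,35,28,,0.064868891146896285,0.25469372027377568,1.0643076345278446,0.28718936059356248,False,False
sim0007,0.67029171301650781,25,24,,0.086251268508897319,0.29368566275679397,2.2823440093212435,0.022469038184890416,True,False
sim0008,0.67468368357889485,30,17,,0.096999395435391517,0.31144725947645052,2.166285504367746,0.030289376716261678,True,False
sim0009,0.72951712414837577,15,68,,0.084578544407714576,0.29082390618330289,2.5084496447433371,0.012126225030668861,True,False
sim0010,0.037979721181036361,23,29,,0.077974889290456692,0.27923984187514628,0.13601111118669754,0.8918124971366832,False,False
sim0011,0.52011626358841834,22,27,,0.08525200012065573,0.29197945153838434,1.781345436632696,0.074856036040028509,False,False
sim0012,0.25338133199926338,18,21,,0.10399770701313805,0.32248675478713551,0.78571081831411438,0.43203692384467562,False,False
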