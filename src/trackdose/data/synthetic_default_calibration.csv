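let_keV_um,response_S
3.5,0.0065479004268543979
4.3366547115878475,0.0090309256516452174
5.373306882153452,0.012455537318658311
6.6577647449423374,0.017178793833633986
8.2492648142278995,0.023693153496993396
10.221203749644934,0.032677819413200304
12.664523256856315,0.045069554871082829
15.691904129102801,0.062160352580227819
19.442962850073844,0.085732140997411208
24.090690414571494,0.11824257255480743
29.849430311930188,0.16308126452599703
36.984763600127209,0.22492320883048095
45.825756949558389,0.3102161981490853
56.780138510680551,0.42785308859167948
70.353101484843862,0.59009899067057914
87.170602579733171,0.81387005978296401
108.00822982552904,1.122497216032182
133.82697107518382,1.5481586831391783
165.81753275735051,2.1352349689128514
205.45525277029617,2.9449360857658236
254.56813998479331,4.0616834566274331
315.42117819577408,5.6019118994057653
390.82078244494119,7.7262094064713365
484.24422502180073,10.656060442324755
600,14.696938456699069
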