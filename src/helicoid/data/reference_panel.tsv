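species	mean_peak_nm	sd_peak_nm	predicted_half_pitch_nm	sd_predicted_nm	observed_half_pitch_nm	sd_observed_nm	arcs_present
Anemia mexicana var. makrinii	482	27	161	9	157	8	1
Antrophyum callifolium	457	29	152	10	156	13	1
Cyclopeltis crenata	486	17	162	6	168	10	1
Elaphoglossum herminieri	474	19	158	6	155	11	1
Lindsaea borneensis	488	23	163	8	163	12	1
Selliguea sp.	472	15	157	5	155	11	1
Tectaria angulata	469	25	156	8	164	14	1
Teratophyllum ludens	536	17	178	6	175	14	1
Bulbophyllum cheiropetalum	499	26	166	9	172	18	1
Dendrobium sp.	500	27	167	9	171	14	1
Masdevallia caesia	458	14	152	5	156	13	1
Porroglossum eduardii	487	17	162	5	164	13	1
Trichosalpinx blaisdellii	485	14	162	5	166	12	1
Carex paniculata	466	33	155	11	150	13	1
Cyperus alternifolius	454	17	151	6	157	13	1
Rhynchospora splendens	568	43	189	14	182	13	1
Scleria motleyi	463	25	154	8	157	14	1
Paepalanthus stegolepoides	476	40	159	14	155	23	1
Phelpsiella ptericaulis	439	12	146	4	144	12	1
Stegolepis pungens	449	23	150	8	158	13	1
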