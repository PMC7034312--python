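# Mean channel locations for the 13-channel left-hemisphere motor/prefrontal fNIRS cap.
# One row per (channel, Brodmann area) assignment; channels with several candidate
# areas span several rows. Probabilities quantify how confidently the estimated MNI
# coordinate falls inside the named area. The BA5 label on CH12 is carried verbatim
# from the source table.
channel	mni_x	mni_y	mni_z	brodmann_label	probability
CH01	-35	59	22	46-Dorsolateral prefrontal cortex	0.844
CH02	-50	46	9	45-Pars triangularis broca's area	0.545
CH02	-50	46	9	46-Dorsolateral prefrontal cortex	0.454
CH03	-41	43	35	46-Dorsolateral prefrontal cortex	0.531
CH03	-41	43	35	45-Pars triangularis broca's area	0.310
CH04	-38	26	52	9-Dorsolateral prefrontal cortex	0.827
CH05	-55	30	23	45-Pars triangularis broca's area	0.920
CH06	-56	21	29	44-Pars opercularis, part of Broca's area	0.732
CH07	-39	12	61	6-Pre-motor and supplementary motor cortex	0.447
CH07	-39	12	61	8-Includes frontal eye fields	0.286
CH07	-39	12	61	9-Dorsolateral prefrontal cortex	0.266
CH08	-36	-4	66	6-Pre-motor and supplementary motor cortex	0.978
CH09	-58	5	39	6-Pre-motor and supplementary motor cortex	0.733
CH10	-59	-5	44	4-Primary motor cortex	0.321
CH10	-59	-5	44	6-Pre-motor and supplementary motor cortex	0.430
CH11	-12	16	70	6-Pre-motor and supplementary motor cortex	0.763
CH12	10	23	67	5-Pre-motor and supplementary motor cortex	0.386
CH12	10	23	67	8-Includes frontal eye fields	0.613
CH13	11	1	75	6-Pre-motor and supplementary motor cortex	1
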