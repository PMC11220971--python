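roi,estimate,p_value
bankssts,0.042,0.448
caudal anterior cingulate,-0.067,0.311
caudal middle frontal,-0.026,0.617
cuneus,0.089,0.102
frontal pole,0.089,0.277
fusiform,0.008,0.870
inferior parietal,0.023,0.615
inferior temporal,0.034,0.543
insula,-0.049,0.309
isthmus cingulate,-0.045,0.377
lateral occipital,0.094,0.156
lateral orbitofrontal,-0.013,0.813
lingual,0.044,0.330
medial orbitofrontal,-0.029,0.643
middle temporal,0.012,0.804
paracentral,-0.137,0.015
parahippocampal,0.029,0.608
pars opercularis,0.043,0.418
pars orbitalis,0.012,0.849
pars triangularis,0.036,0.507
pericalcarine,0.063,0.325
postcentral,-0.057,0.151
posterior cingulate,-0.003,0.946
precentral,0.010,0.786
precuneus,-0.045,0.384
rostral anterior cingulate,-0.024,0.694
rostral middle frontal,-0.001,0.980
superior frontal,-0.016,0.745
superior parietal,-0.006,0.907
superior temporal,0.004,0.934
supramarginal,0.023,0.595
temporal pole,0.004,0.943
transverse temporal,-0.032,0.682
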