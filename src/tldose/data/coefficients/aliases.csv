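alias,canonical
small intestines,small_bowel
small intestine,small_bowel
small bowel,small_bowel
oesophagus,esophagus
esophagus,esophagus
red bone marrow,active_marrow
active bone marrow,active_marrow
active marrow,active_marrow
bone marrow,active_marrow
shallow marrow,bone_surface
bone surface,bone_surface
salivary,salivary_glands
salivary glands,salivary_glands
breast tissue,breast
kidneys,kidney
ovary,ovaries
testis,testes
urinary bladder,bladder
eye lens,lens
lens of eye,lens
spinal cord,spine
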