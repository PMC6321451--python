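# Human pre-miRNAs reported to interact with the DEAD-box helicase DDX1
# (immunoprecipitation study; miRBase nomenclature of the original report,
# which predates current naming — some entries are legacy names).
hsa-miR-82
hsa-miR-96
hsa-miR-101
hsa-miR-129
hsa-miR-138
hsa-miR-141
hsa-miR-146b
hsa-miR-155
hsa-miR-200a
hsa-miR-200b
hsa-miR-200c
hsa-miR-376
hsa-miR-376a
hsa-miR-410
hsa-miR-429
hsa-miR-449a
hsa-miR-487b
hsa-miR-490
hsa-miR-495
hsa-miR-499
hsa-miR-518e
hsa-miR-524
hsa-miR-539
hsa-miR-542
hsa-miR-590
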