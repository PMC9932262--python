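region,population
Aneurin Bevan,476139
Betsi Cadwaladr,571244
Powys,111070
Hywel Dda,318593
Abertawe Bro Morgannwg,437054
Cwm Taf,242199
Cardiff and Vale,399772
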