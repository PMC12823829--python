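name,type,response_min
Bergen,big city,10.2
Tokke,mountain,16.6
Lurøy,island,32.8
Sørfold,rural,22.6
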