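name,expected_direction,ambiguous
shikimic acid,accumulation,false
L-tyrosine,accumulation,false
L-phenylalanine,accumulation,false
tryptamine,accumulation,false
N-benzoyltryptamine,accumulation,false
N-feruloyltryptamine,accumulation,false
kynurenine,accumulation,false
"cyanidin 3,5-di-O-hexoside",consumption,false
epicatechin O-hexoside derivative,accumulation,false
methylisohaenkeanoside,accumulation,false
flavonoid (unresolved 1),accumulation,true
flavonoid (unresolved 2),accumulation,true
flavonoid (unresolved 3),accumulation,true
flavonoid (unresolved 4),accumulation,true
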