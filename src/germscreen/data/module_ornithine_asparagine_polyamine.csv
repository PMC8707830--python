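name,expected_direction,ambiguous
ornithine,consumption,false
L-asparagine,consumption,false
Asn + 2hexoside,consumption,false
putrescine,accumulation,false
spermidine,accumulation,false
agmatine,accumulation,false
N-acetylspermine,special,false
polyamine derivative (unresolved 1),accumulation,true
polyamine derivative (unresolved 2),accumulation,true
polyamine derivative (unresolved 3),accumulation,true
polyamine derivative (unresolved 4),accumulation,true
polyamine derivative (unresolved 5),accumulation,true
polyamine derivative (unresolved 6),accumulation,true
polyamine derivative (unresolved 7),accumulation,true
polyamine derivative (unresolved 8),accumulation,true
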