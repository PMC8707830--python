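compound_class,count
amino acids and derivatives,16
polyamines,12
lipids,9
flavonoids,7
organic acids,6
terpenes,5
nucleotides and derivatives,3
phytohormones,2
sugars,2
vitamins and derivatives,2
others,10
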