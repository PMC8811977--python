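# Destination split of annual live-pool turnover into DOM pools.
# Fractions per source pool must sum to 1.
source_pool,destination_pool,fraction
Merchantable,SnagStem,1.0
Foliage,AbovegroundVeryFast,1.0
OtherWood,SnagBranch,0.25
OtherWood,AbovegroundFast,0.75
CoarseRoot,AbovegroundFast,0.5
CoarseRoot,BelowgroundFast,0.5
FineRoot,AbovegroundVeryFast,0.5
FineRoot,BelowgroundVeryFast,0.5
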