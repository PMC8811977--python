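# Transition-triggered carbon flows, applied simultaneously to the
# pre-transition state at the end of a timestep.  destination is a pool
# name, "atmosphere" (direct combustion emission) or "export" (transfer out
# of the ecosystem to harvested wood products).  Proportions per
# (transition_type, source_pool) must sum to <= 1; the remainder stays put.
# Documented defaults for testing and demos; override for science use.
transition_type,source_pool,destination,proportion
fire_high,Merchantable,atmosphere,0.10
fire_high,Merchantable,SnagStem,0.90
fire_high,Foliage,atmosphere,0.90
fire_high,Foliage,AbovegroundVeryFast,0.10
fire_high,OtherWood,atmosphere,0.25
fire_high,OtherWood,SnagBranch,0.50
fire_high,OtherWood,AbovegroundFast,0.25
fire_high,CoarseRoot,BelowgroundFast,1.0
fire_high,FineRoot,BelowgroundVeryFast,1.0
fire_high,SnagStem,atmosphere,0.20
fire_high,SnagBranch,atmosphere,0.40
fire_high,AbovegroundMedium,atmosphere,0.30
fire_high,AbovegroundFast,atmosphere,0.60
fire_high,AbovegroundVeryFast,atmosphere,0.85
fire_high,AbovegroundSlow,atmosphere,0.05
fire_medium,Merchantable,atmosphere,0.05
fire_medium,Merchantable,SnagStem,0.45
fire_medium,Foliage,atmosphere,0.45
fire_medium,Foliage,AbovegroundVeryFast,0.05
fire_medium,OtherWood,atmosphere,0.12
fire_medium,OtherWood,SnagBranch,0.25
fire_medium,OtherWood,AbovegroundFast,0.13
fire_medium,CoarseRoot,BelowgroundFast,0.5
fire_medium,FineRoot,BelowgroundVeryFast,0.5
fire_medium,SnagStem,atmosphere,0.10
fire_medium,SnagBranch,atmosphere,0.20
fire_medium,AbovegroundMedium,atmosphere,0.15
fire_medium,AbovegroundFast,atmosphere,0.35
fire_medium,AbovegroundVeryFast,atmosphere,0.55
fire_medium,AbovegroundSlow,atmosphere,0.03
fire_low,Merchantable,atmosphere,0.02
fire_low,Merchantable,SnagStem,0.13
fire_low,Foliage,atmosphere,0.15
fire_low,Foliage,AbovegroundVeryFast,0.05
fire_low,OtherWood,atmosphere,0.05
fire_low,OtherWood,SnagBranch,0.08
fire_low,OtherWood,AbovegroundFast,0.05
fire_low,CoarseRoot,BelowgroundFast,0.15
fire_low,FineRoot,BelowgroundVeryFast,0.15
fire_low,SnagStem,atmosphere,0.05
fire_low,SnagBranch,atmosphere,0.10
fire_low,AbovegroundMedium,atmosphere,0.08
fire_low,AbovegroundFast,atmosphere,0.20
fire_low,AbovegroundVeryFast,atmosphere,0.35
fire_low,AbovegroundSlow,atmosphere,0.02
clearcut,Merchantable,export,0.85
clearcut,Merchantable,AbovegroundMedium,0.15
clearcut,Foliage,AbovegroundVeryFast,1.0
clearcut,OtherWood,export,0.10
clearcut,OtherWood,AbovegroundFast,0.45
clearcut,OtherWood,AbovegroundMedium,0.45
clearcut,CoarseRoot,AbovegroundFast,0.5
clearcut,CoarseRoot,BelowgroundFast,0.5
clearcut,FineRoot,AbovegroundVeryFast,0.5
clearcut,FineRoot,BelowgroundVeryFast,0.5
selection_harvest,Merchantable,export,0.30
selection_harvest,Merchantable,AbovegroundMedium,0.03
selection_harvest,Foliage,AbovegroundVeryFast,0.30
selection_harvest,OtherWood,export,0.03
selection_harvest,OtherWood,AbovegroundFast,0.27
selection_harvest,CoarseRoot,AbovegroundFast,0.15
selection_harvest,CoarseRoot,BelowgroundFast,0.15
selection_harvest,FineRoot,AbovegroundVeryFast,0.15
selection_harvest,FineRoot,BelowgroundVeryFast,0.15
insect_high,Merchantable,SnagStem,0.9
insect_high,Foliage,AbovegroundVeryFast,0.9
insect_high,OtherWood,SnagBranch,0.45
insect_high,OtherWood,AbovegroundFast,0.45
insect_high,CoarseRoot,AbovegroundFast,0.45
insect_high,CoarseRoot,BelowgroundFast,0.45
insect_high,FineRoot,AbovegroundVeryFast,0.45
insect_high,FineRoot,BelowgroundVeryFast,0.45
insect_medium,Merchantable,SnagStem,0.5
insect_medium,Foliage,AbovegroundVeryFast,0.5
insect_medium,OtherWood,SnagBranch,0.25
insect_medium,OtherWood,AbovegroundFast,0.25
insect_medium,CoarseRoot,AbovegroundFast,0.25
insect_medium,CoarseRoot,BelowgroundFast,0.25
insect_medium,FineRoot,AbovegroundVeryFast,0.25
insect_medium,FineRoot,BelowgroundVeryFast,0.25
insect_low,Merchantable,SnagStem,0.2
insect_low,Foliage,AbovegroundVeryFast,0.2
insect_low,OtherWood,SnagBranch,0.1
insect_low,OtherWood,AbovegroundFast,0.1
insect_low,CoarseRoot,AbovegroundFast,0.1
insect_low,CoarseRoot,BelowgroundFast,0.1
insect_low,FineRoot,AbovegroundVeryFast,0.1
insect_low,FineRoot,BelowgroundVeryFast,0.1
urbanization,Merchantable,export,0.30
urbanization,Merchantable,atmosphere,0.20
urbanization,Merchantable,AbovegroundMedium,0.50
urbanization,Foliage,atmosphere,0.50
urbanization,Foliage,AbovegroundVeryFast,0.50
urbanization,OtherWood,export,0.10
urbanization,OtherWood,atmosphere,0.40
urbanization,OtherWood,AbovegroundFast,0.50
urbanization,CoarseRoot,atmosphere,0.20
urbanization,CoarseRoot,BelowgroundFast,0.80
urbanization,FineRoot,BelowgroundVeryFast,1.0
agricultural_expansion,Merchantable,export,0.25
agricultural_expansion,Merchantable,atmosphere,0.25
agricultural_expansion,Merchantable,AbovegroundMedium,0.50
agricultural_expansion,Foliage,atmosphere,0.60
agricultural_expansion,Foliage,AbovegroundVeryFast,0.40
agricultural_expansion,OtherWood,export,0.10
agricultural_expansion,OtherWood,atmosphere,0.45
agricultural_expansion,OtherWood,AbovegroundFast,0.45
agricultural_expansion,CoarseRoot,atmosphere,0.25
agricultural_expansion,CoarseRoot,BelowgroundFast,0.75
agricultural_expansion,FineRoot,BelowgroundVeryFast,1.0
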