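# Base carbon flow rates (all 1/yr, dimensionless fractions).  Rows with
# species_name=default apply to every species lacking an override row.
# parameter values:
#   turnover        - annual live-pool biomass turnover rate (pool = live pool)
#   snag_fall       - standing-dead fall rate (SnagStem -> AbovegroundMedium,
#                     SnagBranch -> AbovegroundFast)
#   base_decay_rate - DOM decay rate at the 10 degC reference temperature
#   p_air           - proportion of decayed carbon emitted to the atmosphere;
#                     the remainder transfers to the slow pool on the same
#                     side of the ground surface
#   q10             - temperature sensitivity of decay for the pool
#   slow_mixing     - AbovegroundSlow -> BelowgroundSlow transfer rate
# Defaults are plausible boreal/temperate stock-flow values; override per
# species for science use.
species_name,parameter,pool,value
default,turnover,Merchantable,0.006
default,turnover,Foliage,0.095
default,turnover,OtherWood,0.035
default,turnover,CoarseRoot,0.02
default,turnover,FineRoot,0.641
default,snag_fall,SnagStem,0.032
default,snag_fall,SnagBranch,0.10
default,base_decay_rate,SnagStem,0.0187
default,base_decay_rate,SnagBranch,0.0718
default,base_decay_rate,AbovegroundMedium,0.0374
default,base_decay_rate,AbovegroundFast,0.1435
default,base_decay_rate,AbovegroundVeryFast,0.355
default,base_decay_rate,AbovegroundSlow,0.015
default,base_decay_rate,BelowgroundFast,0.1435
default,base_decay_rate,BelowgroundVeryFast,0.5
default,base_decay_rate,BelowgroundSlow,0.006
default,p_air,SnagStem,0.83
default,p_air,SnagBranch,0.83
default,p_air,AbovegroundMedium,0.83
default,p_air,AbovegroundFast,0.83
default,p_air,AbovegroundVeryFast,0.83
default,p_air,AbovegroundSlow,1.0
default,p_air,BelowgroundFast,0.83
default,p_air,BelowgroundVeryFast,0.83
default,p_air,BelowgroundSlow,1.0
default,q10,SnagStem,2.0
default,q10,SnagBranch,2.0
default,q10,AbovegroundMedium,2.0
default,q10,AbovegroundFast,2.0
default,q10,AbovegroundVeryFast,2.65
default,q10,AbovegroundSlow,2.65
default,q10,BelowgroundFast,2.0
default,q10,BelowgroundVeryFast,2.0
default,q10,BelowgroundSlow,2.0
default,slow_mixing,AbovegroundSlow,0.006
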