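# Default volume-to-biomass expansion scheme.  Each factor converts
# merchantable stem volume (m3/ha) to component biomass (tons/ha); the
# carbon fraction then converts biomass to carbon.  These are documented,
# plausible temperate-forest defaults intended for testing and demos; for
# science use supply a species-specific file with the same schema.  A row
# with species_name=default applies to any species without its own row.
species_name,foliage,merchantable,other_wood,coarse_root,fine_root,carbon_fraction
default,0.035,0.42,0.16,0.085,0.012,0.5
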