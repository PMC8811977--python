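species_name,ecozone,province,cbm_species,a,b,mean_temp_c,mri_years
Forest: White/Red/Jack Pine Group,Mixedwood Plains,Ontario,Jack pine,239.99,0.04,6.81,125
Forest: Spruce/Fir Group,Atlantic Maritime,Quebec,Spruce - Genus type,120.32,0.03,4.64,125
Forest: Longleaf/Slash Pine Group,Mixedwood Plains,Ontario,Pine - Genus type,148.94,0.08,19.62,125
Forest: Loblolly/Shortleaf Pine Group,Mixedwood Plains,Ontario,Pine - Genus type,225.70,0.08,17.47,125
Forest: Pinyon/Juniper Group,Montane Cordillera,British Columbia,Other softwoods,56.62,0.02,9.74,150
Forest: Douglas-fir Group,Pacific Maritime,British Columbia,Douglas-fir - Genus type,597.10,0.03,7.17,300
Forest: Ponderosa Pine Group,Montane Cordillera,British Columbia,Ponderosa pine,152.73,0.03,7.56,150
Forest: Western White Pine Group,Pacific Maritime,British Columbia,Western white pine,228.52,0.02,9.75,300
Forest: Fir/Spruce/Mountain Hemlock Group,Montane Cordillera,British Columbia,Mountain hemlock,241.10,0.03,3.80,150
Forest: Lodgepole Pine Group,Montane Cordillera,British Columbia,Lodgepole pine,203.42,0.03,3.14,150
Forest: Hemlock/Sitka Spruce Group,Pacific Maritime,British Columbia,Sitka spruce,736.44,0.04,8.38,300
Forest: Western Larch Group,Montane Cordillera,British Columbia,Western larch,298.51,0.03,5.31,150
Forest: Redwood Group,Pacific Maritime,British Columbia,Other softwoods,1907.28,0.01,12.69,1000
Forest: Other Western Softwood Group,Montane Cordillera,British Columbia,Other softwoods,138.36,0.01,2.47,150
Forest: California Mixed Conifer Group,Montane Cordillera,British Columbia,Other softwoods,477.09,0.02,10.40,150
Forest: Exotic Softwoods Group,Montane Cordillera,British Columbia,Other softwoods,363.02,0.03,7.63,150
Forest: Oak/Pine Group,Mixedwood Plains,Ontario,Oak,191.02,0.05,16.80,125
Forest: Oak/Hickory Group,Mixedwood Plains,Ontario,Hickory,206.02,0.04,13.22,125
Forest: Oak/Gum/Cypress Group,Mixedwood Plains,Ontario,Cypress,289.99,0.03,18.33,125
Forest: Elm/Ash/Cottonwood Group,Mixedwood Plains,Ontario,Ash,155.53,0.05,14.23,125
Forest: Maple/Beech/Birch Group,Atlantic Maritime,Quebec,Maple,229.04,0.03,6.71,125
Forest: Aspen/Birch Group,Boreal Shield West,Ontario,Birch,146.48,0.04,5.15,75
Forest: Alder/Maple Group,Pacific Maritime,British Columbia,Alder,436.17,0.05,10.47,300
Forest: Western Oak Group,Montane Cordillera,British Columbia,Oak,130.24,0.02,12.89,150
Forest: Tanoak/Laurel Group,Pacific Maritime,British Columbia,Other hardwoods,476.90,0.04,13.12,300
Forest: Other Western Hardwoods Group,Montane Cordillera,British Columbia,Other hardwoods,130.24,0.02,12.81,150
Forest: Tropical Hardwoods Group,Mixedwood Plains,Ontario,Other hardwoods,206.48,0.02,22.08,125
Forest: Exotic Hardwoods Group,Mixedwood Plains,Ontario,Other hardwoods,67.94,0.09,19.23,125
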