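category,resistance,is_habitat
Broadleaf,1,True
Mixed woodland,1,True
Coniferous,1,True
Orchard,16,False
Scrub,16,False
Coppice,16,False
Garden,16,False
Improved/Arable/Amenity,40,False
Grass,40,False
Heath,37,False
Path,27,False
Railway verge,27,False
Road verge,27,False
Marsh,91,False
Water,130,False
Urban,72,False
Railway,55,False
Track,27,False
Building,1000,False
Rock,1000,False
Field edge,16,False
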