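Community,Description,SL,Zone
TR,"Large organogenic build-ups of Lithophyllum byssoides, Lithophyllum trochanter, Dendropoma",20,mediolittoral
CB,Community dominated by Cystoseira brachycarpa / crinita / elegans,20,infralittoral
Cs,Community dominated by Cystoseira foeniculacea / barbata / humilis / spinosa,20,infralittoral
CA5,Continuous belt of Cystoseira amentacea / mediterranea,20,infralittoral
CA4,Almost continuous belt of Cystoseira amentacea / mediterranea,19,infralittoral
CA3,Abundant patches of dense stands of Cystoseira amentacea / mediterranea,15,infralittoral
CA2,Abundant scattered plants of Cystoseira amentacea / mediterranea,12,infralittoral
CC,Community dominated by Cystoseira compressa,12,infralittoral
CA1,Rare scattered plants of Cystoseira amentacea / mediterranea,10,infralittoral
DS,Community dominated by Padina / Dictyota / Dictyopteris / Taonia / Stypocaulon,10,infralittoral
Cor,Community dominated by Corallina spp. (including Ellisolandia elongata),8,infralittoral
EC,"Community dominated by Lithophyllum incrustans, Neogoniolithon brassica-florida and other encrusting corallines",6,infralittoral
Mgal,Community dominated by Mytilus galloprovincialis,6,infralittoral
Ulva,Community dominated by Pterocladiella / Ulva / Schizymenia,6,infralittoral
GA,Community dominated by Ulva and / or Cladophora,3,infralittoral
BG,Community dominated by Cyanobacteria and Derbesia tenuissima,1,infralittoral
Pos,Barrier and fringing reefs of Posidonia oceanica,20,infralittoral
Cym,Superficial Cymodocea nodosa meadows,20,infralittoral
Zos,Superficial Zostera noltii meadows,20,infralittoral
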