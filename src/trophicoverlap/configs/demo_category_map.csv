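taxon,category
unid. bony fish,Fish
engraulidae,Fish
clupeidae,Fish
syacium spp.,Fish
serranidae,Fish
sparidae,Fish
portunus spp.,Crab
callinectes similis,Crab
xanthidae,Crab
paguridae,Crab
majidae,Crab
penaeidae,Shrimp
sicyonia spp.,Shrimp
alpheidae,Shrimp
gammaridea,Amphipod
caprellidae,Amphipod
hyperiidea,Amphipod
conus spp.,Gastropod
nassarius spp.,Gastropod
turridae,Gastropod
calanoida,Copepod
harpacticoida,Copepod
euphausiidae,Krill
squilla empusa,Mantis Shrimp
stomatopoda larvae,Mantis Shrimp
ostracoda,Ostracod
ascidiacea,Tunicate
cirripedia,Barnacle
bivalvia,Bivalve
bryozoa,Bryozoan
loliginidae,Cephalopod
chaetognatha,Chaetognath
cumacea,Cumacean
megalopae,Decapod Larvae
ophiuroidea,Echinoderm
fish eggs,Fish Eggs
hydrozoa,Hydroid
isopoda,Isopod
mysidacea,Mysid
polychaeta,Polychaete
nereididae,Polychaete
pteropoda,Pteropod
pycnogonida,Pycnogonid
salpidae,Salp
sipuncula,Sipunculid
zoea larvae,Zoea
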