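habitat,taxon,metabolism,cells_per_m3,cell_radius_um,citation
oligotrophic,Bacterioplankton,heterotroph,4.7e10,0.5,9
oligotrophic,Bacterioplankton,heterotroph,2.0e11,0.5,10
oligotrophic,Diatoms,phototroph,5.6e7,10.0,11
oligotrophic,Dinoflagellates,phototroph,6.5e6,10.0,11
oligotrophic,PicoEukaryotes,phototroph,6.7e8,2.0,12
oligotrophic,PicoEukaryotes,phototroph,2.0e9,2.0,10
oligotrophic,Prochlorococcus,phototroph,4.7e10,0.3,12
oligotrophic,Prochlorococcus,phototroph,3.8e10,0.3,10
oligotrophic,Silicoflagellates,phototroph,1.3e7,10.0,11
oligotrophic,Synechococcus,phototroph,3.0e9,1.0,12
oligotrophic,Synechococcus,phototroph,2.0e9,1.0,10
mesotrophic,Bacterioplankton,heterotroph,3.3e11,0.5,10
mesotrophic,PicoEukaryotes,phototroph,3.0e9,2.0,10
mesotrophic,Prochlorococcus,phototroph,3.1e10,0.3,10
mesotrophic,Synechococcus,phototroph,6.0e9,1.0,10
eutrophic,Bacterioplankton,heterotroph,4.6e11,0.5,10
eutrophic,Bacterioplankton,heterotroph,4.6e13,0.5,13
eutrophic,Chlorophytes,phototroph,8.2e10,2.5,14
eutrophic,Chroococcales,phototroph,8.2e10,1.0,14
eutrophic,Cyanobium,phototroph,4.0e12,1.0,14
eutrophic,PicoEukaryotes,phototroph,3.0e9,2.0,10
eutrophic,PicoEukaryotes,phototroph,1.5e13,2.0,13
eutrophic,Synechococcus,phototroph,4.5e9,1.0,10
colony,Cyanobium,phototroph,1.0e13,1.0,14
colony,Phaeocystis,phototroph,2.4e13,2.2,8
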