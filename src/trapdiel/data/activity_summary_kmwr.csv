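species,vernacular,total_detections,independent_detections,d_sunrise,d_day,d_sunset,d_night,u2,u2_p_below_001,activity_cycle,diet
Dicotyles tajacu,Southern collared peccary,1003,200,-0.42,0.21,0.42,-0.45,1.64,1,mostly diurnal,herbivore
Nasua narica,White-nosed coati,345,80,-0.42,0.84,-0.45,-0.94,1.91,1,diurnal,omnivore
Dasyprocta punctata,Central American agouti,154,80,-0.05,0.57,0.40,-1.00,1.41,1,mostly diurnal,herbivore
Odocoileus virginianus,White-tailed deer,102,49,-0.37,0.38,0.23,-0.48,0.36,1,mostly diurnal,herbivore
Didelphis marsupialis,Common opossum,20,15,,,,,,,nocturnal,omnivore
Leopardus pardalis,Ocelot,23,14,,,,,,,nocturnal,carnivore
Tamandua mexicana,Northern tamandua,13,11,,,,,,,mostly nocturnal,carnivore
Cuniculus paca,Paca,11,11,,,,,,,nocturnal,herbivore
Puma concolor,Puma,11,7,,,,,,,cathemeral,carnivore
Eira barbara,Tayra,5,4,,,,,,,diurnal,omnivore
Conepatus semistriatus,Striped hog-nosed skunk,3,3,,,,,,,nocturnal,omnivore
Cebus imitator,Panamanian white-faced capuchin,2,1,,,,,,,diurnal,omnivore
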