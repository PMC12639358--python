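order,family,species,vernacular,methods,ct2019
DIDELPHIMORPHIA,Didelphidae,Caluromys derbianus,Derby's woolly opossum,DO,0
DIDELPHIMORPHIA,Didelphidae,Didelphis marsupialis,Common opossum,CT;DO;TS,1
DIDELPHIMORPHIA,Didelphidae,Philander opossum,Gray four-eyed opossum,DO,0
DIDELPHIMORPHIA,Didelphidae,Marmosa zeledoni,Zeledon's mouse opossum,DO,0
PILOSA,Myrmecophagidae,Tamandua mexicana,Northern tamandua,CT;DO;TS,1
CINGULATA,Dasypodidae,Dasypus novemcinctus,Nine-banded armadillo,DO;TS,0
ARTIODACTYLA,Cervidae,Odocoileus virginianus,White-tailed deer,CT;DO;TS,1
ARTIODACTYLA,Tayassuidae,Dicotyles tajacu,Southern collared peccary,CT;DO;TS,1
PRIMATES,Cebidae,Cebus imitator,Panamanian white-faced capuchin,CT;DO;TS,1
PRIMATES,Atelidae,Alouatta palliata,Mantled howler,DO;TS;VO,0
CARNIVORA,Canidae,Canis latrans,Coyote,DO;TS;VO,0
CARNIVORA,Canidae,Urocyon cinereoargenteus,Gray fox,DO,0
CARNIVORA,Felidae,Leopardus wiedii,Margay,DO,0
CARNIVORA,Felidae,Leopardus pardalis,Ocelot,CT;DO;TS,1
CARNIVORA,Felidae,Herpailurus yagouaroundi,Jaguarundi,CT;DO;TS,0
CARNIVORA,Felidae,Puma concolor,Puma,CT;TS,1
CARNIVORA,Mephitidae,Conepatus semistriatus,Striped hog-nosed skunk,CT;DO;TS,1
CARNIVORA,Mephitidae,Spilogale angustifrons,Southern spotted skunk,CT;DO,1
CARNIVORA,Mustelidae,Eira barbara,Tayra,CT;DO;TS,1
CARNIVORA,Mustelidae,Lontra annectens,Northern neotropical river otter,CT;TS,0
CARNIVORA,Procyonidae,Nasua narica,White-nosed coati,CT;DO;TS,1
CARNIVORA,Procyonidae,Potos flavus,Kinkajou,DO,0
CARNIVORA,Procyonidae,Procyon lotor,Northern raccoon,CT;DO;TS,0
RODENTIA,Heteromyidae,Heteromys salvini,Salvin's spiny pocket mouse,DO,0
RODENTIA,Cricetidae,Oryzomys couesi,Coues's rice rat,DO,0
RODENTIA,Cricetidae,Sigmodon hirsutus,Southern cotton rat,DO,0
RODENTIA,Erethizontidae,Coendou mexicanus,Mexican hairy porcupine,DO,0
RODENTIA,Dasyproctidae,Dasyprocta punctata,Central American agouti,CT;DO;TS,1
RODENTIA,Cuniculidae,Cuniculus paca,Paca,CT;DO;TS,1
RODENTIA,Sciuridae,Sciurus variegatoides,Variegated squirrel,DO,0
CHIROPTERA,Emballonuridae,Balantiopteryx plicata,Gray Sac-winged bat,DO,0
CHIROPTERA,Emballonuridae,Diclidurus albus,Northern ghost bat,DO;MI,0
CHIROPTERA,Emballonuridae,Saccopteryx bilineata,Greater Sac-winged bat,DO;MI,0
CHIROPTERA,Natalidae,Natalus mexicanus,Mexican funnel-eared bat,DO,0
CHIROPTERA,Noctilionidae,Noctilio leporinus,Greater bulldog bat,DO,0
CHIROPTERA,Phyllostomidae,Artibeus jamaicensis,Jamaican fruit-eating bat,DO;MI,0
CHIROPTERA,Phyllostomidae,Artibeus lituratus,Gray fruit-eating bat,DO,0
CHIROPTERA,Phyllostomidae,Carollia perspicillata,Seba's short-tailed bat,DO;MI,0
CHIROPTERA,Phyllostomidae,Carollia sowelli,Sowell's short-tailed bat,MI,0
CHIROPTERA,Phyllostomidae,Carollia subrufa,Gray short-tailed bat,MI,0
CHIROPTERA,Phyllostomidae,Chrotopterus auritus,Big-eared woolly bat,DO,0
CHIROPTERA,Phyllostomidae,Dermanura phaeotis,Pygmy fruit-eating bat,MI,0
CHIROPTERA,Phyllostomidae,Dermanura watsoni,Thomas's fruit-eating bat,MI,0
CHIROPTERA,Phyllostomidae,Desmodus rotundus,Common vampire bat,DO;MI,0
CHIROPTERA,Phyllostomidae,Diphylla ecaudata,Hairy-legged vampire bat,DO,0
CHIROPTERA,Phyllostomidae,Glossophaga commissarisi,Commissaris's long-tongued bat,MI,0
CHIROPTERA,Phyllostomidae,Glossophaga leachii,Gray long-tongued bat,DO,0
CHIROPTERA,Phyllostomidae,Glossophaga soricina,Pallas's long-tongued bat,DO;MI,0
CHIROPTERA,Phyllostomidae,Phyllostomus discolor,Pale spear-nosed bat,MI,0
CHIROPTERA,Phyllostomidae,Phyllostomus hastatus,Greater spear-nosed bat,DO,0
CHIROPTERA,Phyllostomidae,Platyrrhinus helleri,Heller's broad-nosed bat,DO;MI,0
CHIROPTERA,Phyllostomidae,Sturnira parvidens,Northern yellow-shouldered bat,DO;MI,0
CHIROPTERA,Phyllostomidae,Trachops cirrhosus,Fringe-lipped bat,MI,0
CHIROPTERA,Phyllostomidae,Uroderma convexum,Mesoamerican tent-making bat,DO;MI,0
CHIROPTERA,Phyllostomidae,Vampyriscus nymphaea,Stripe yellow-eared bat,DO,0
CHIROPTERA,Phyllostomidae,Vampyrum spectrum,Spectral bat,DO;MI,0
CHIROPTERA,Vespertilionidae,Myotis albescens,Silver-tipped myotis,DO,0
CHIROPTERA,Vespertilionidae,Myotis elegans,Elegant myotis,MI,0
CHIROPTERA,Vespertilionidae,Myotis riparius,Riparian myotis,MI,0
CHIROPTERA,Vespertilionidae,Rhogeessa bickhami,Bickham's little yellow bat,MI,0
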