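taxon,functional_group
Clupeidae,forage_finfish
Alosa alabamae,forage_finfish
Alosa chrysochloris,forage_finfish
Clupea harengus,forage_finfish
Brevoortia,forage_finfish
Brevoortia gunteri,forage_finfish
Brevoortia patronus,forage_finfish
Dorosoma cepedianum,forage_finfish
Dorosoma petenense,forage_finfish
Opisthonema oglinum,forage_finfish
Harengula jaguana,forage_finfish
Sardinella aurita,forage_finfish
Anchoa,forage_finfish
Anchoa hepsetus,forage_finfish
Anchoa mitchilli,forage_finfish
Anchoa lyolepis,forage_finfish
Anchoa nasuta,forage_finfish
Membras martinica,forage_finfish
Menidia,forage_finfish
Menidia beryllina,forage_finfish
Menidia peninsulae,forage_finfish
Mugil cephalus,forage_finfish
Polydactylus octonemus,forage_finfish
Peprilus paru,forage_finfish
Peprilus triacanthus,forage_finfish
Peprilus burti,forage_finfish
Engraulidae,forage_finfish
Pomatomus saltatrix,pelagic
Rachycentron canadum,pelagic
Caranx hippos,pelagic
Caranx latus,pelagic
Caranx crysos,pelagic
Chloroscombrus chrysurus,pelagic
Oligoplites saurus,pelagic
Selene vomer,pelagic
Selene setapinnis,pelagic
Trachinotus carolinus,pelagic
Trachinotus falcatus,pelagic
Decapterus punctatus,pelagic
Hemicaranx amblyrhynchus,pelagic
Trichiurus lepturus,pelagic
Scomberomorus cavalla,pelagic
Scomberomorus maculatus,pelagic
Sphyraena guachancho,pelagic
Sphyraena borealis,pelagic
Echeneis naucrates,pelagic
Echeneis neucratoides,pelagic
Elops saurus,pelagic
Megalops atlanticus,pelagic
Centropomus undecimalis,pelagic
Penaeidae,shrimp
Xiphopenaeus kroyeri,shrimp
Acetes americanus,shrimp
Sicyonia brevirostris,shrimp
Sicyonia dorsalis,shrimp
Sicyonia laevigata,shrimp
Macrobrachium,shrimp
Macrobrachium ohione,shrimp
Palaemonetes,shrimp
Palaemonetes intermedius,shrimp
Palaemonetes paludosus,shrimp
Palaemonetes pugio,shrimp
Palaemonetes vulgaris,shrimp
Palaemon floridanus,shrimp
Alpheidae,shrimp
Alpheus heterochaelis,shrimp
Alpheus estuariensis,shrimp
Hippolyte zostericola,shrimp
Lysmata wurdemanni,shrimp
Tozeuma carolinense,shrimp
Rimapenaeus,shrimp
Farfantepenaeus aztecus,shrimp
Farfantepenaeus duorarum,shrimp
Rimapenaeus constrictus,shrimp
Rimapenaeus similis,shrimp
Litopenaeus setiferus,shrimp
Farfantepenaeus,shrimp
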