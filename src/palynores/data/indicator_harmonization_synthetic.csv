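hl0,hl1,hl2,status,group
Plantago lanceolata-type,Plantago lanceolata-type,Plantago,ADVENTIVE,UPLAND_HERB
Plantago major-type,Plantago major/media-type,Plantago,ADVENTIVE,UPLAND_HERB
Plantago media-type,Plantago major/media-type,Plantago,ADVENTIVE,UPLAND_HERB
Plantago maritima-type,Plantago maritima-type,Plantago,NONE,UPLAND_HERB
Plantago atrata-type,Plantago atrata-type,Plantago,NONE,UPLAND_HERB
Plantago alpina-type,Plantago alpina-type,Plantago,APOPHYTE,UPLAND_HERB
Plantago montana-type,Plantago montana-type,Plantago,APOPHYTE,UPLAND_HERB
Hordeum-type,Cerealia-type,Poaceae,PRIMARY_INTRODUCED,UPLAND_HERB
Triticum-type,Cerealia-type,Poaceae,PRIMARY_INTRODUCED,UPLAND_HERB
Avena-type,Cerealia-type,Poaceae,PRIMARY_INTRODUCED,UPLAND_HERB
Secale,Secale,Poaceae,PRIMARY_INTRODUCED,UPLAND_HERB
Poaceae,Poaceae,Poaceae,NONE,UPLAND_HERB
Artemisia,Artemisia,Artemisia,APOPHYTE,UPLAND_HERB
Adonis,Adonis,Adonis,APOPHYTE,UPLAND_HERB
Caltha-type,Caltha-type,Caltha-type,APOPHYTE,UPLAND_HERB
Ranunculus arvensis-type,Ranunculus arvensis-type,Ranunculus arvensis-type,APOPHYTE,UPLAND_HERB
Nigella,Nigella,Nigella,ADVENTIVE,UPLAND_HERB
Fagopyrum,Fagopyrum,Fagopyrum,PRIMARY_INTRODUCED,UPLAND_HERB
Olea europaea,Olea europaea,Olea europaea,PRIMARY_NATIVE,TREE
Castanea sativa,Castanea sativa,Castanea sativa,PRIMARY_NATIVE,TREE
Ficus carica,Ficus carica,Ficus carica,PRIMARY_INTRODUCED,TREE
Vitis,Vitis,Vitis,PRIMARY_NATIVE,SHRUB
Pistacia,Pistacia,Pistacia,PRIMARY_NATIVE,SHRUB
Juglans regia,Juglans regia,Juglans regia,PRIMARY_INTRODUCED,TREE
Linum usitatissimum-type,Linum usitatissimum-type,Linum,PRIMARY_INTRODUCED,UPLAND_HERB
Linum austriacum-type,Linum austriacum-type,Linum,NONE,UPLAND_HERB
Agrostemma githago,Agrostemma githago,Caryophyllaceae,ADVENTIVE,UPLAND_HERB
Scleranthus,Scleranthus,Caryophyllaceae,ADVENTIVE,UPLAND_HERB
Spergula arvensis,Spergula arvensis,Caryophyllaceae,ADVENTIVE,UPLAND_HERB
Caryophyllaceae undiff.,Caryophyllaceae undiff.,Caryophyllaceae,NONE,UPLAND_HERB
Fallopia,Fallopia,Polygonum-type,ADVENTIVE,UPLAND_HERB
Polygonum aviculare-type,Polygonum aviculare-type,Polygonum-type,ADVENTIVE,UPLAND_HERB
Persicaria maculosa-type,Persicaria maculosa-type,Polygonum-type,ADVENTIVE,UPLAND_HERB
Polygonum viviparum-type,Polygonum viviparum-type,Polygonum-type,NONE,UPLAND_HERB
Rumex acetosa-type,Rumex acetosa-type,Rumex/Oxyria,APOPHYTE,UPLAND_HERB
Rumex acetosella-type,Rumex acetosella-type,Rumex/Oxyria,APOPHYTE,UPLAND_HERB
Oxyria-type,Oxyria-type,Rumex/Oxyria,NONE,UPLAND_HERB
Torilis japonica,Torilis japonica,Apiaceae,ADVENTIVE,UPLAND_HERB
Apiaceae undiff.,Apiaceae undiff.,Apiaceae,NONE,UPLAND_HERB
Cannabis sativa-type,Cannabis/Humulus-type,Cannabis/Humulus-type,PRIMARY_INTRODUCED,UPLAND_HERB
Humulus lupulus-type,Cannabis/Humulus-type,Cannabis/Humulus-type,NONE,UPLAND_HERB
Centaurea cyanus-type,Centaurea cyanus-type,Centaurea,ADVENTIVE,UPLAND_HERB
Centaurea montana-type,Centaurea montana-type,Centaurea,NONE,UPLAND_HERB
Sinapis-type,Brassicaceae,Brassicaceae,ADVENTIVE,UPLAND_HERB
Hornungia-type,Brassicaceae,Brassicaceae,NONE,UPLAND_HERB
Carex-type,Cyperaceae,Cyperaceae,APOPHYTE,UPLAND_HERB
Eriophorum,Cyperaceae,Cyperaceae,APOPHYTE,UPLAND_HERB
Cyperaceae undiff.,Cyperaceae,Cyperaceae,NONE,UPLAND_HERB
Succisa pratensis,Succisa pratensis,Succisa pratensis,APOPHYTE,UPLAND_HERB
Calluna vulgaris,Calluna vulgaris,Ericaceae,APOPHYTE,SHRUB
Erica-type,Erica-type,Ericaceae,NONE,SHRUB
Melampyrum pratense-type,Melampyrum pratense-type,Melampyrum,APOPHYTE,UPLAND_HERB
Urtica,Urtica,Urtica,APOPHYTE,UPLAND_HERB
Trifolium repens-type,Trifolium repens-type,Trifolium-type,APOPHYTE,UPLAND_HERB
Juniperus,Juniperus,Juniperus,APOPHYTE,SHRUB
Pteridium aquilinum,Pteridium aquilinum,Pteridium aquilinum,APOPHYTE,TERRESTRIAL_FERN
Polypodium vulgare,Polypodium vulgare,Polypodium vulgare,APOPHYTE,TERRESTRIAL_FERN
Vicia faba,Vicia faba,Vicia-type,PRIMARY_INTRODUCED,UPLAND_HERB
Vicia sylvatica-type,Vicia sylvatica-type,Vicia-type,NONE,UPLAND_HERB
Quercus,Quercus,Quercus,NONE,TREE
Pinus,Pinus,Pinus,NONE,TREE
Betula,Betula,Betula,NONE,TREE
Alnus,Alnus,Alnus,NONE,TREE
Fagus,Fagus,Fagus,NONE,TREE
Abies,Abies,Abies,NONE,TREE
Picea,Picea,Picea,NONE,TREE
Corylus,Corylus,Corylus,NONE,SHRUB
Nymphaea,Nymphaea,Nymphaea,NONE,EXCLUDED
Myriophyllum,Myriophyllum,Myriophyllum,NONE,EXCLUDED
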