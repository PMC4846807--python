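species,genus,family
Abies fargesii,Abies,Pinaceae
Acer caesium,Acer,Aceraceae
Acer davidii,Acer,Aceraceae
Acer grosseri,Acer,Aceraceae
Acer maximowiczii,Acer,Aceraceae
Acer mono,Acer,Aceraceae
Betula albosinensis,Betula,Betulaceae
Betula luminifera,Betula,Betulaceae
Betula platyphylla,Betula,Betulaceae
Betula utilis,Betula,Betulaceae
Bothrocaryum controversum,Bothrocaryum,Cornaceae
Carpinus turczaninowii,Carpinus,Betulaceae
Catalpa fargesii,Catalpa,Bignoniaceae
Cerasus polytricha,Cerasus,Rosaceae
Cerasus tomentosa,Cerasus,Rosaceae
Cornus kousa,Cornus,Cornaceae
Corylus chinensis,Corylus,Betulaceae
Crataegus kansuensis,Crataegus,Rosaceae
Euonymus phellomanus,Euonymus,Celastraceae
Fraxinus chinensis,Fraxinus,Oleaceae
Juglans cathayensis,Juglans,Juglandaceae
Juglans regia,Juglans,Juglandaceae
Kalopanax septemlobus,Kalopanax,Araliaceae
Larix chinensis,Larix,Pinaceae
Lindera glauca,Lindera,Lauraceae
Lindera obtusiloba,Lindera,Lauraceae
Litsea pungens,Litsea,Lauraceae
Malus baccata,Malus,Rosaceae
Malus kansuensis,Malus,Rosaceae
Meliosma cuneifolia,Meliosma,Sabiaceae
Padus obtusata,Padus,Rosaceae
Pinus armandii,Pinus,Pinaceae
Pinus tabuliformis,Pinus,Pinaceae
Populus davidiana,Populus,Salicaceae
Populus purdomii,Populus,Salicaceae
Pterocarya hupehensis,Pterocarya,Juglandaceae
Quercus aliena var. acutiserrata,Quercus,Fagaceae
Quercus spinosa,Quercus,Fagaceae
Quercus variabilis,Quercus,Fagaceae
Rhus potaninii,Rhus,Anacardiaceae
Salix caprea,Salix,Salicaceae
Salix wallichiana,Salix,Salicaceae
Sorbus alnifolia,Sorbus,Rosaceae
Sorbus folgneri,Sorbus,Rosaceae
Sorbus koehneana,Sorbus,Rosaceae
Swida macrophylla,Swida,Cornaceae
Tilia chinensis,Tilia,Tiliaceae
Tilia paucicostata,Tilia,Tiliaceae
Toxicodendron vernicifluum,Toxicodendron,Anacardiaceae
Tsuga chinensis,Tsuga,Pinaceae
Ulmus bergmanniana,Ulmus,Ulmaceae
Dendrobenthamia japonica,Dendrobenthamia,Cornaceae
Carpinus cordata,Carpinus,Betulaceae
Pinus massoniana,Pinus,Pinaceae
Quercus glandulifera,Quercus,Fagaceae
Alnus cremastogyne,Alnus,Betulaceae
Ostrya japonica,Ostrya,Betulaceae
Carpinus fargesiana,Carpinus,Betulaceae
Corylus heterophylla,Corylus,Betulaceae
Acer ginnala,Acer,Aceraceae
Acer oliverianum,Acer,Aceraceae
Acer tetramerum,Acer,Aceraceae
Sorbus hupehensis,Sorbus,Rosaceae
Pyrus betulifolia,Pyrus,Rosaceae
Prunus salicina,Prunus,Rosaceae
Crataegus pinnatifida,Crataegus,Rosaceae
Malus hupehensis,Malus,Rosaceae
Quercus wutaishanica,Quercus,Fagaceae
Castanea seguinii,Castanea,Fagaceae
Fagus engleriana,Fagus,Fagaceae
Lindera communis,Lindera,Lauraceae
Litsea tsinlingensis,Litsea,Lauraceae
Sassafras tzumu,Sassafras,Lauraceae
Juglans mandshurica,Juglans,Juglandaceae
Pterocarya stenoptera,Pterocarya,Juglandaceae
Cornus walteri,Cornus,Cornaceae
Swida alba,Swida,Cornaceae
Tilia oliveri,Tilia,Tiliaceae
Tilia tuan,Tilia,Tiliaceae
Salix matsudana,Salix,Salicaceae
Populus cathayana,Populus,Salicaceae
Ulmus pumila,Ulmus,Ulmaceae
Zelkova sinica,Zelkova,Ulmaceae
Celtis sinensis,Celtis,Ulmaceae
Fraxinus mandschurica,Fraxinus,Oleaceae
Syringa reticulata,Syringa,Oleaceae
Euonymus maackii,Euonymus,Celastraceae
Kalopanax pictus,Kalopanax,Araliaceae
Catalpa ovata,Catalpa,Bignoniaceae
Rhus chinensis,Rhus,Anacardiaceae
Phellodendron amurense,Phellodendron,Rutaceae
Ailanthus altissima,Ailanthus,Simaroubaceae
Eucommia ulmoides,Eucommia,Eucommiaceae
Euptelea pleiosperma,Euptelea,Eupteleaceae
Morus australis,Morus,Moraceae
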