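common_name,latin_name,electrical_response,n_recordings,n_plants
Araucaria,Araucaria araucana,No,11,3
Argentinian Dollar,Plectranthus purpuratus,Yes,30,3
Basil,Ocimum basilicum,Yes,42,6
Fern,Polypodiopsida,No,7,2
Ivy,Hedera,No,10,3
Lemon Balm,Melissa officinalis,No,11,4
Mint,Mentha spicata,Yes,28,16
Oregano,Origanum vulgare,No,5,5
Papyrus,Cyperus papyrus,No,10,2
Radiators,Peperomia,No,8,2
Rosemary,Salvia rosmarinus,Yes,37,8
Ruda,Ruta graveolens,Yes,42,5
Sensitive Mimosa,Mimosa pudica,Yes,40,6
Sundew,Drosera capensis,Yes,20,9
Tomato,Solanum lycopersicum,Yes,27,10
Venus Flytrap,Dionaea muscipula,Yes,70,5
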