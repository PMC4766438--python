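inchikey	name	cas	cid	smiles
MLFHJEHSLIIPHL-UHFFFAOYSA-N	isopentyl acetate	123-92-2|29732-50-1		CC(C)CCOC(C)=O
OSWPMRLSEDHDFF-UHFFFAOYSA-N	methyl salicylate			COC(=O)c1ccccc1O
DKPFZGUDAPQIHT-UHFFFAOYSA-N	butyl acetate			CCCCOC(C)=O
FKRCODPIKNYEAC-UHFFFAOYSA-N	ethyl propionate			CCOC(=O)CC
ULDHMXUKGWMISQ-VIFPVBQESA-N	(S)-(+)-carvone			CC1=CC[C@@H](CC1=O)C(=C)C
QNVRIHYSUZMSGM-UHFFFAOYSA-N	2-hexanol			CCCCC(C)O
GWYFCOCPABKNJV-UHFFFAOYSA-N	isopentanoic acid			CC(C)CC(O)=O
CATSNJVOTSVZJV-UHFFFAOYSA-N	2-heptanone			CCCCCC(C)=O
KWOLFJPFCHCOCG-UHFFFAOYSA-N	acetophenone			CC(=O)c1ccccc1
QTBSBXVTEAMEQO-UHFFFAOYSA-N	acetic acid			CC(O)=O
KIDHWZJUCRJVML-UHFFFAOYSA-N	putrescine			NCCCCN
HIGQPQRQIQDZMP-DHZHZOJOSA-N	geranyl acetate			CC(=O)OC/C=C(C)/CCC=C(C)C
CURLTUGMZLYLDI-UHFFFAOYSA-N	carbon dioxide			O=C=O
RWRDLPDLKQPQOW-UHFFFAOYSA-N	pyrrolidine			C1CCNC1
ZSIAUFGUXNUGDI-UHFFFAOYSA-N	1-hexanol			CCCCCCO
SHZIWNPUGXLXDT-UHFFFAOYSA-N	ethyl hexanoate			CCCCCC(=O)OCC
KXKVLQRXCPHEJC-UHFFFAOYSA-N	methyl acetate			COC(C)=O
PFCHFHIRKBAQGU-UHFFFAOYSA-N	3-hexanone			CCCC(=O)CC
QSJXEFYPDANLFS-UHFFFAOYSA-N	2,3-butanedione			CC(=O)C(C)=O
OMSUIQOIVADKIM-UHFFFAOYSA-N	ethyl 3-hydroxybutyrate			CCOC(=O)CC(C)O
IWDCLRJOBJJRNH-UHFFFAOYSA-N	4-methylphenol			Cc1ccc(O)cc1
QWVGKYWNOKOFNN-UHFFFAOYSA-N	2-methylphenol			Cc1ccccc1O
MTZQAGJQAFMTAQ-UHFFFAOYSA-N	ethyl benzoate			CCOC(=O)c1ccccc1
VSMOENVRRABVKN-UHFFFAOYSA-N	1-octen-3-ol			C=CC(O)CCCCC
AMQJEAYHLZJPGS-UHFFFAOYSA-N	1-pentanol			CCCCCO
DTUQWGWMVIHBKE-UHFFFAOYSA-N	phenylacetaldehyde			O=CCc1ccccc1
ROWKJAVDOGWPAT-UHFFFAOYSA-N	3-hydroxy-2-butanone			CC(O)C(C)=O
PGMYKACGEOXYJE-UHFFFAOYSA-N	pentyl acetate			CCCCCOC(C)=O
OBNCKNCVKJNDBV-UHFFFAOYSA-N	ethyl butyrate			CCCC(=O)OCC
ROSDSFDQCJNGOL-UHFFFAOYSA-N	dimethylamine			CNC
JLPUXFOGCDVKGO-GRYCIOLGSA-N	geosmin
LYRIITRHDCNUHV-UHFFFAOYSA-N	ethyl 3-hydroxyhexanoate
LHXDLQBQYFFVNW-OIBJUYFYSA-N	(1R)-(-)-fenchone
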