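# Relatedness of Beauveria pseudobassiana RGM 2184 to 27 entomopathogenic
# fungal strains: ANIb (%), dDDH (%), and percentage of RGM 2184 genes with a
# BSR homolog (exoenzymes, toxins, NRPS, PKS), by strain taxonomy.
strain	species	genus	family	order	subphylum	anib	ddh	exo_pct	toxin_pct	nrps_pct	pks_pct
Beauveria pseudobassiana KACC 47484	Beauveria pseudobassiana	Beauveria	Cordycipitaceae	Hypocreales	Pezizomycotina	96	70	98	80	100	95
Beauveria brongniartii RCEF 3172	Beauveria brongniartii	Beauveria	Cordycipitaceae	Hypocreales	Pezizomycotina	89	37	95	70	80	90
Beauveria bassiana ARSEF 2860	Beauveria bassiana	Beauveria	Cordycipitaceae	Hypocreales	Pezizomycotina	88	34	93	60	88	80
Beauveria bassiana ARSEF 1520	Beauveria bassiana	Beauveria	Cordycipitaceae	Hypocreales	Pezizomycotina	88	34	93	65	88	85
Akanthomyces lecanii RCEF 1005	Akanthomyces lecanii	Akanthomyces	Cordycipitaceae	Hypocreales	Pezizomycotina	78	21	65	30	60	45
Cordyceps javanica IJ1G	Cordyceps javanica	Cordyceps	Cordycipitaceae	Hypocreales	Pezizomycotina	78	21	61	35	68	45
Cordyceps javanica IJ2G	Cordyceps javanica	Cordyceps	Cordycipitaceae	Hypocreales	Pezizomycotina	78	21	61	35	68	45
Cordyceps militaris CM01	Cordyceps militaris	Cordyceps	Cordycipitaceae	Hypocreales	Pezizomycotina	78	21	54	25	72	70
Akanthomyces lecanii UM487	Akanthomyces lecanii	Akanthomyces	Cordycipitaceae	Hypocreales	Pezizomycotina	78	22	38	25	56	40
Cordyceps fumosorosea ARSEF 2679	Cordyceps fumosorosea	Cordyceps	Cordycipitaceae	Hypocreales	Pezizomycotina	78	21	53	20	68	60
Lecanicillium psalliotae HWLR35	Lecanicillium psalliotae	Lecanicillium	Cordycipitaceae	Hypocreales	Pezizomycotina	77	21	42	25	64	50
Tolypocladium paradoxum NRBC 100945	Tolypocladium paradoxum	Tolypocladium	Ophiocordycipitaceae	Hypocreales	Pezizomycotina	71	20	0	15	24	40
Purpureocillium lilacinum PLFJ-1	Purpureocillium lilacinum	Purpureocillium	Ophiocordycipitaceae	Hypocreales	Pezizomycotina	71	20	0	10	20	50
Sporothrix insectorum RCEF 264	Sporothrix insectorum	Sporothrix	Ophiostomataceae	Ophiostomatales	Pezizomycotina	70	19	0	0	8	50
Metarhizium album ARSEF 1941	Metarhizium album	Metarhizium	Clavicipitaceae	Hypocreales	Pezizomycotina	70	20	0	10	24	45
Moelleriella libera RCEF 2490	Moelleriella libera	Moelleriella	Clavicipitaceae	Hypocreales	Pezizomycotina	70	20	0	10	24	50
Metarhizium rileyi RCEF 4871	Metarhizium rileyi	Metarhizium	Clavicipitaceae	Hypocreales	Pezizomycotina	70	22	0	24	20	45
Metarhizium rileyi Cep018-CH2	Metarhizium rileyi	Metarhizium	Clavicipitaceae	Hypocreales	Pezizomycotina	70	22	0	15	20	45
Metarhizium brunneum ARSEF 3297	Metarhizium brunneum	Metarhizium	Clavicipitaceae	Hypocreales	Pezizomycotina	70	21	1	30	20	50
Metarhizium robertsii ARSEF 2575	Metarhizium robertsii	Metarhizium	Clavicipitaceae	Hypocreales	Pezizomycotina	70	22	0	20	20	50
Metarhizium robertsii ARSEF 23	Metarhizium robertsii	Metarhizium	Clavicipitaceae	Hypocreales	Pezizomycotina	70	22	0	20	20	50
Metarhizium anisopliae ARSEF 549	Metarhizium anisopliae	Metarhizium	Clavicipitaceae	Hypocreales	Pezizomycotina	70	21	1	20	20	50
Metarhizium anisopliae BRIP 53293	Metarhizium anisopliae	Metarhizium	Clavicipitaceae	Hypocreales	Pezizomycotina	70	21	1	15	20	50
Ophiocordyceps polyrhachis-furcata BCC 54312	Ophiocordyceps polyrhachis-furcata	Ophiocordyceps	Ophiocordycipitaceae	Hypocreales	Pezizomycotina	70	19	14	10	16	50
Metarhizium acridum CQMa 102	Metarhizium acridum	Metarhizium	Clavicipitaceae	Hypocreales	Pezizomycotina	70	21	2	20	20	45
Aspergillus flavus NRRL 118543	Aspergillus flavus	Aspergillus	Aspergillaceae	Eurotiales	Pezizomycotina	67	20	0	0	16	60
Aspergillus flavus NRRL3357	Aspergillus flavus	Aspergillus	Aspergillaceae	Eurotiales	Pezizomycotina	67	19	0	0	16	55
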