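accession,gene,protein,p_value,fold_change,d_eucl_printed,higher_in
P22676,CALB2,Calretinin,0.0004,22.4,3.64,epithelioid
O43790,KRT86,"Keratin, type II cuticular Hb6",0.0148,110.5,2.74,epithelioid
P08727,RT19,"Keratin, type I cytoskeletal 19",0.0047,24.2,2.71,epithelioid
P13647,KRT5,"Keratin, type II cytoskeletal 5",0.0232,15.7,2.03,epithelioid
P05787,KRT8,"Keratin, type II cytoskeletal 8",0.0484,6.9,1.56,epithelioid
P51970,NDUFA8,"NADH dehydrogenase [ubiquinone] 1 alpha subcomplex subunit 8",0.0012,4.9,2.99,epithelioid
P22735,TGM1,Protein-glutamine gamma-glutamyltransferase,0.0015,6.7,2.93,epithelioid
Q9Y4L1,HYOU1,Hypoxia up-regulated protein 1,0.0120,3.8,2.01,epithelioid
P12109,COL6A1,Collagen alpha-1(VI) chain,0.0238,4.2,1.74,sarcomatoid
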