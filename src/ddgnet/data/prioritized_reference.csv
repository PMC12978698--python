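trajectory,boundary_label,gene,eqtl_tissue,eqtl_rcp,sqtl_tissue,sqtl_h4pp
1,LMP_to_OBP,Tet1,Adipose (Visceral),0.3191,,
1,LMP_to_OBP,Tpx2,Testis,0.2031,,
1,LMP_to_OBP,Cdk1,,,Pituitary,0.7795
1,LMP_to_OBP,Ttyh3,,,Liver,0.9350
1,LMP_to_OBP,Olfml3,Artery (aorta),0.8048,,
1,LMP_to_OBP,Izumo4,,,Brain (hypothalamus),0.9182
1,LMP_to_OBP,Sec24d,Nerve (tibial),0.2677,,
1,LMP_to_OBP,Tmem263,Adipose (subcutaneous),0.5704,Cultured cells (fibroblasts),0.9716
1,LMP_to_OBP,Lmf2,,,Adrenal gland,0.8181
1,LMP_to_OBP,Tln2,Esophagus (muscularis),0.9697,,
1,OBP_to_OB1,Kremen1,Heart (left ventricle),0.8686,,
2,OBP_to_OB2,Kremen1,Heart (left ventricle),0.8686,,
2,OBP_to_OB2,Ebf1,,,Testis,0.8760
2,OBP_to_OB2,Lrp4,Pancreas,0.7943,,
3,LMP_to_MALP,Ttyh3,,,Liver,0.9350
3,LMP_to_MALP,Fgfrl1,Cultured cells (fibroblasts),0.1611,,
3,LMP_to_MALP,Ebf1,,,Testis,0.8760
3,LMP_to_MALP,Ppp1r12b,,,Nerve (tibial),0.8807
3,LMP_to_MALP,Rhoj,Cultured cells (fibroblasts),0.352,Breast,0.7844
3,LMP_to_MALP,Tln2,Esophagus (muscularis),0.9697,,
3,MALP_to_end,Adh1,,,Esophagus (gastroesophageal junction),0.9999
3,MALP_to_end,Fgfrl1,Cultured cells (fibroblasts),0.1611,,
3,MALP_to_end,Adcy5,,,Esophagus (gastroesophageal junction),0.8456
3,MALP_to_end,Cnn2,,,Spleen,0.7743
3,MALP_to_end,Mxra8,,,Pituitary,0.7545
3,MALP_to_end,Timp2,,,Testis,0.9429
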