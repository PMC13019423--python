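# Mid-IR band assignments of EV samples isolated by TEIR, UC, and SEC, plus the albumin reference bands.
# Columns: method,modality,wavenumber,assignment ; wavenumber is cm-1 or a range "a-b".
method,modality,wavenumber,assignment
TEIR,AFM-IR,1767,CO stretching-phospholipid-membrane packing
SEC,AFM-IR,1767,CO stretching-phospholipid-membrane packing
UC,FTIR,1770,CO stretching-phospholipid-membrane packing
TEIR,FTIR,1745,CO stretching-phospholipid
TEIR,AFM-IR,1743,CO stretching-phospholipid
UC,FTIR,1745,CO stretching-phospholipid
SEC,FTIR,1745,CO stretching-phospholipid
SEC,AFM-IR,1743,CO stretching-phospholipid
TEIR,FTIR,1692,Amide I - β-sheet (antiparallel)
TEIR,AFM-IR,1700,Amide I - β-sheet (antiparallel)
UC,FTIR,1695,Amide I - β-sheet (antiparallel)
UC,AFM-IR,1700,Amide I - β-sheet (antiparallel)
SEC,FTIR,1693,Amide I - β-sheet (antiparallel)
SEC,AFM-IR,1700,Amide I - β-sheet (antiparallel)
TEIR,FTIR,1667,Amide I random coil/turn/loop (protein-lipid interaction)
TEIR,AFM-IR,1680,Amide I random coil/turn/loop (protein-lipid interaction)
UC,FTIR,1639-1660,Amide I random coil/turn/loop (protein-lipid interaction)
UC,AFM-IR,1665,Amide I random coil/turn/loop (protein-lipid interaction)
SEC,FTIR,1639-1660,Amide I random coil/turn/loop (protein-lipid interaction)
SEC,AFM-IR,1676,Amide I random coil/turn/loop (protein-lipid interaction)
TEIR,FTIR,1642,Amide I α-helix
TEIR,AFM-IR,1645,Amide I α-helix
UC,FTIR,1632,Amide I α-helix
UC,AFM-IR,1645,Amide I α-helix
SEC,FTIR,1636,Amide I α-helix
TEIR,AFM-IR,1600-1615,"CN, CC, nucleic acids"
UC,AFM-IR,1600-1615,"CN, CC, nucleic acids"
SEC,AFM-IR,1600-1615,"CN, CC, nucleic acids"
TEIR,FTIR,1542,Amide II - proteins
TEIR,AFM-IR,1550-1575,Amide II - proteins
UC,FTIR,1542,Amide II - proteins
UC,AFM-IR,1550-1575,Amide II - proteins
SEC,FTIR,1542,Amide II - proteins
SEC,AFM-IR,1550-1575,Amide II - proteins
TEIR,FTIR,1520,Amide II α-helix/β-sheet ratio
TEIR,AFM-IR,1530,Amide II α-helix/β-sheet ratio
UC,FTIR,1520,Amide II α-helix/β-sheet ratio
SEC,FTIR,1520,Amide II α-helix/β-sheet ratio
TEIR,FTIR,1397,deprotonated carboxylic groups in fatty acids or phospholipids
TEIR,AFM-IR,1400-1430,deprotonated carboxylic groups in fatty acids or phospholipids
UC,FTIR,1397,deprotonated carboxylic groups in fatty acids or phospholipids
UC,AFM-IR,1400-1430,deprotonated carboxylic groups in fatty acids or phospholipids
SEC,FTIR,1397,deprotonated carboxylic groups in fatty acids or phospholipids
SEC,AFM-IR,1400-1430,deprotonated carboxylic groups in fatty acids or phospholipids
TEIR,FTIR,1373-1395,CH/CH3 - lipid methylation
TEIR,AFM-IR,1373-1395,CH/CH3 - lipid methylation
UC,FTIR,1373-1395,CH/CH3 - lipid methylation
UC,AFM-IR,1373-1395,CH/CH3 - lipid methylation
SEC,FTIR,1373-1395,CH/CH3 - lipid methylation
SEC,AFM-IR,1373-1395,CH/CH3 - lipid methylation
TEIR,FTIR,1281,"Asymmetric SO, sulfated lipids glycosaminoglycans"
TEIR,AFM-IR,1295,"Asymmetric SO, sulfated lipids glycosaminoglycans"
UC,FTIR,1280,"Asymmetric SO, sulfated lipids glycosaminoglycans"
UC,AFM-IR,1289,"Asymmetric SO, sulfated lipids glycosaminoglycans"
SEC,FTIR,1285,"Asymmetric SO, sulfated lipids glycosaminoglycans"
SEC,AFM-IR,1292,"Asymmetric SO, sulfated lipids glycosaminoglycans"
TEIR,FTIR,1251,"Asymmetric SO, sulfated lipids glycosaminoglycans"
TEIR,AFM-IR,1257,"Asymmetric SO, sulfated lipids glycosaminoglycans"
UC,FTIR,1251,"Asymmetric SO, sulfated lipids glycosaminoglycans"
UC,AFM-IR,1277,"Asymmetric SO, sulfated lipids glycosaminoglycans"
SEC,FTIR,1251,"Asymmetric SO, sulfated lipids glycosaminoglycans"
SEC,AFM-IR,1260,"Asymmetric SO, sulfated lipids glycosaminoglycans"
TEIR,FTIR,1205,"Asymmetric SO, sulfated lipids glycosaminoglycans"
TEIR,AFM-IR,1204,"Asymmetric SO, sulfated lipids glycosaminoglycans"
UC,FTIR,1200,"Asymmetric SO, sulfated lipids glycosaminoglycans"
UC,AFM-IR,1200,"Asymmetric SO, sulfated lipids glycosaminoglycans"
SEC,FTIR,1200,"Asymmetric SO, sulfated lipids glycosaminoglycans"
SEC,AFM-IR,1200,"Asymmetric SO, sulfated lipids glycosaminoglycans"
UC,AFM-IR,1168,"Asymmetric SO, sulfated lipids glycosaminoglycans"
TEIR,FTIR,1144,"C-O stretch/PO2- of phospholipids, nucleic acids"
TEIR,AFM-IR,1123,"C-O stretch/PO2- of phospholipids, nucleic acids"
UC,FTIR,1122,"C-O stretch/PO2- of phospholipids, nucleic acids"
UC,AFM-IR,1130,"C-O stretch/PO2- of phospholipids, nucleic acids"
SEC,FTIR,1119,"C-O stretch/PO2- of phospholipids, nucleic acids"
SEC,AFM-IR,1129,"C-O stretch/PO2- of phospholipids, nucleic acids"
UC,AFM-IR,1116,"C-O stretch/PO2- of phospholipids, nucleic acids"
TEIR,FTIR,1100,"υPO2-; phosphate vibration; symmetric phosphate [PO2- (sym)] stretching; collagen and phosphodiester groups of nucleic acids"
TEIR,AFM-IR,1078,"υPO2-; phosphate vibration; symmetric phosphate [PO2- (sym)] stretching; collagen and phosphodiester groups of nucleic acids"
UC,FTIR,1100,"υPO2-; phosphate vibration; symmetric phosphate [PO2- (sym)] stretching; collagen and phosphodiester groups of nucleic acids"
UC,AFM-IR,1080,"υPO2-; phosphate vibration; symmetric phosphate [PO2- (sym)] stretching; collagen and phosphodiester groups of nucleic acids"
SEC,FTIR,1100,"υPO2-; phosphate vibration; symmetric phosphate [PO2- (sym)] stretching; collagen and phosphodiester groups of nucleic acids"
SEC,AFM-IR,1084,"υPO2-; phosphate vibration; symmetric phosphate [PO2- (sym)] stretching; collagen and phosphodiester groups of nucleic acids"
TEIR,FTIR,1032,C-O stretch/PO2- of glycosidic linkages
TEIR,AFM-IR,1035,C-O stretch/PO2- of glycosidic linkages
UC,FTIR,1027,C-O stretch/PO2- of glycosidic linkages
UC,AFM-IR,1038,C-O stretch/PO2- of glycosidic linkages
SEC,FTIR,1030,C-O stretch/PO2- of glycosidic linkages
SEC,AFM-IR,1038,C-O stretch/PO2- of glycosidic linkages
TEIR,FTIR,989,O-P-O symmetric stretching of phospholipids
TEIR,AFM-IR,978,O-P-O symmetric stretching of phospholipids
UC,FTIR,989,O-P-O symmetric stretching of phospholipids
UC,AFM-IR,982,O-P-O symmetric stretching of phospholipids
SEC,FTIR,989,O-P-O symmetric stretching of phospholipids
SEC,AFM-IR,977,O-P-O symmetric stretching of phospholipids
albumin,FTIR,1650,Amide I - albumin
albumin,FTIR,1550,Amide II - albumin
albumin,FTIR,1450,CH2 and CH3 scissoring
albumin,FTIR,1070,υPO2- (PBS buffer)
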