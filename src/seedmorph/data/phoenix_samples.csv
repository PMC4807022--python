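sample_id,species,status,role,n_seeds,origin,label
0081_CON1,dactylifera,cultivated,cultivar,20,Spain,La Confitera
0072_IBE4,dactylifera,cultivated,cultivar,20,Spain,Iberica
0076_BFE1,dactylifera,cultivated,cultivar,20,Morocco,Bou Feggous
0083_MED1,dactylifera,cultivated,cultivar,20,Morocco,Medjoul
0080_THO1,dactylifera,cultivated,cultivar,20,Algeria,Thorry
0212_GME2,dactylifera,cultivated,cultivar,20,Algeria,Ghars Mettig
1249_AHM4,dactylifera,cultivated,cultivar,20,Mauritania,Ahmar
1254_TIJ2,dactylifera,cultivated,cultivar,20,Mauritania,Tijib
0186_DEG2,dactylifera,cultivated,cultivar,20,Tunisia,Deglet Nour
0216_LAG2,dactylifera,cultivated,cultivar,20,Tunisia,Lagou
1550_TIS1,dactylifera,cultivated,cultivar,20,Libya,Tiswin
1552_DIG1,dactylifera,cultivated,cultivar,20,Libya,Digla
0097_SHE1,dactylifera,cultivated,cultivar,20,Egypt,Shelabi
0007_SIW3,dactylifera,cultivated,cultivar,20,Egypt,Siwi
0093_IBR1,dactylifera,cultivated,cultivar,20,Syria,Ibrahimi
0094_OMA1,dactylifera,cultivated,cultivar,20,Syria,Om Asal
0198_HAL2,dactylifera,cultivated,cultivar,20,Iraq,Halaoui
0079_ZAY1,dactylifera,cultivated,cultivar,20,Iraq,Zaydi
0077_KHA1,dactylifera,cultivated,cultivar,11,Saudi Arabia,Khalass
0095_QAD1,dactylifera,cultivated,cultivar,20,Saudi Arabia,Qadi
0122_NBA1,dactylifera,cultivated,cultivar,20,Oman,Nashu Al Khasba
0139_KAB1,dactylifera,cultivated,cultivar,20,Oman,Khasab
1549_MAZ1,dactylifera,cultivated,cultivar,20,Iran,Mozafati
0107_ISW1,dactylifera,cultivated,cultivar,20,Iran,Iswid
1601_DAC492,dactylifera,cultivated,seedling,20,India,Seedling
1625_DAC514,dactylifera,cultivated,seedling,20,India,Seedling
2431-DAC832,dactylifera,feral,feral,20,Egypt,Feral
2433-DAC834,dactylifera,feral,feral,20,Egypt,Feral
344-WILD63,dactylifera,uncultivated_unknown,uncultivated,20,Oman,Uncultivated
403-WILD82,dactylifera,uncultivated_unknown,uncultivated,20,Oman,Uncultivated
1267_ACA4,acaulis,wild_reference,wild,15,India,
1720_ACA6,acaulis,wild_reference,wild,20,India,
1867_ACA7,acaulis,wild_reference,wild,20,India,
1871-ACA8,acaulis,wild_reference,wild,7,India,
2139_AND2,andamanensis,wild_reference,wild,13,India,
1322_CAE3,caespitosa,wild_reference,wild,20,Somalia,
1878_CAE4,caespitosa,wild_reference,wild,20,Somalia,
1879_CAE5,caespitosa,wild_reference,wild,20,Somalia,
0721_CAN8,canariensis,wild_reference,wild,20,Italy,
0880_CAN37,canariensis,wild_reference,wild,20,Italy,
0092_CAN1,canariensis,wild_reference,wild,20,France,
1870_CAN62,canariensis,wild_reference,wild,20,Canary Islands,
1875_CAN63,canariensis,wild_reference,wild,20,Canary Islands,
1722_LOR12,loureiroi,wild_reference,wild,20,India,
1863_LOR14,loureiroi,wild_reference,wild,20,India,
1864_LOR15,loureiroi,wild_reference,wild,20,India,
2140_LOR17,loureiroi,wild_reference,wild,20,Bhutan,
1865_LOR16,loureiroi,wild_reference,wild,20,Philippines,
2143_LOR18,loureiroi,wild_reference,wild,20,Thailand,
1868_PAL4,paludosa,wild_reference,wild,20,,
1869_PAL5,paludosa,wild_reference,wild,20,,
1872_PAL6,paludosa,wild_reference,wild,10,Vietnam,
2144_PAL7,paludosa,wild_reference,wild,20,Thailand,
1873_PUS5,pusilla,wild_reference,wild,20,,
1874_PUS6,pusilla,wild_reference,wild,20,Sri Lanka,
2141_PUS7,pusilla,wild_reference,wild,20,Sri Lanka,
2142_PUS8,pusilla,wild_reference,wild,20,India,
2145_PUS9,pusilla,wild_reference,wild,20,Sri Lanka,
0441_REC1,reclinata,wild_reference,wild,20,Madagascar,
0443_REC2,reclinata,wild_reference,wild,20,Benin,
0766_REC14,reclinata,wild_reference,wild,20,Italy,
0771_REC15,reclinata,wild_reference,wild,20,Italy,
1321_REC40,reclinata,wild_reference,wild,20,Tanzania,
1719_REC42,reclinata,wild_reference,wild,20,Gabon,
0906_ROE4,roebelenii,wild_reference,wild,20,Italy,
1721_RUP10,rupicola,wild_reference,wild,9,India,
1866_RUP11,rupicola,wild_reference,wild,20,India,
1876_RUP12,rupicola,wild_reference,wild,20,India,
1877_RUP13,rupicola,wild_reference,wild,20,India,
1653_SYL20,sylvestris,wild_reference,wild,20,India,
1680_SYL47,sylvestris,wild_reference,wild,20,India,
1688_SYL55,sylvestris,wild_reference,wild,20,India,
1689_SYL56,sylvestris,wild_reference,wild,20,India,
1696_SYL63,sylvestris,wild_reference,wild,20,India,
1702_SYL69,sylvestris,wild_reference,wild,20,India,
1709_SYL76,sylvestris,wild_reference,wild,20,India,
1712_SYL79,sylvestris,wild_reference,wild,20,India,
1714_SYL81,sylvestris,wild_reference,wild,20,India,
1718_SYL85,sylvestris,wild_reference,wild,20,India,
1461_THE19,theophrasti,wild_reference,wild,20,Greece,
1462_THE20,theophrasti,wild_reference,wild,20,Greece,
1478_THE36,theophrasti,wild_reference,wild,20,Greece,
1479_THE37,theophrasti,wild_reference,wild,20,Greece,
2146_THE82,theophrasti,wild_reference,wild,20,Greece,
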