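name,BP,EV,FP,MR,SA,MV,P
Lenalidomide,614,91.1,325.1,66.5,93,177.5,26.3
Thalidomide,487.8,79.4,248.8,65.2,87,161,25.9
Cabozantinib,758.1,110.4,412.3,137,99,359,54.3
Sorafenib,523.3,79.7,290.3,113.1,92,319.5,44.8
Sunitinib,521.1,85.8,299.8,112.5,77,324.1,44.6
Axitinib,668.9,98.3,358.3,113.5,96,284.8,45
Lenvatinib,627.2,92.8,333.1,112,116,280.6,44.4
Erlotinib,553.6,83.4,288.6,101.1,75,315.4,43.6
Neratinib,757,110.3,411.6,155.1,112,416.8,61.5
Ifosfamide,386.5,57.9,157.1,58.1,51,195.7,23
Cytarabine,543.7,98.2,283.8,52.6,112,128.4,20.9
Docetaxel,900.5,137.1,498.4,205.2,224,585.7,81.4
Paclitaxel,957.1,146,532.6,219.3,222,610.6,86.9
Valrubicin,867.7,132.1,478.6,169.8,245,469.8,65.3
Mitomycin C,581.8,87,305.6,80.8,147,213.7,32
Erdafitinib,662.3,97.4,354.4,129.6,77,389.7,51.4
Gemcitabine,482.7,86.2,245.7,52.1,108,142.3,20.6
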