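name,M1,M2,H,F,SS,ABC,RI,SC,GA,HZ,reconstructed
Lenalidomide,104,126,8.7000,276,22.5761,15.0442,9.0754,9.5272,20.3025,528,
Thalidomide,104,127,8.7333,276,22.61,15.0037,9.0922,9.541,20.3429,530,
Cabozantinib,200,240,17.3714,526,43.9331,29.075,17.9122,18.7906,39.9043,1006,
Sorafenib,164,187,14.419,434,35.6701,24.7041,15.1512,15.6105,32.5468,808,
Sunitinib,150,178,13.2667,392,32.8726,22.1842,13.8498,14.2734,29.9329,748,
Axitinib,146,171,13.5362,362,33.0132,21.8679,13.7415,14.4185,30.5058,704,F
Lenvatinib,160,189,13.9333,414,35.2178,23.5699,14.4399,15.1157,32.023,792,
Erlotinib,142,163,14,344,32.5554,21.799,14.245,14.665,30.5254,670,
Neratinib,202,233,18.8,506,45.3206,30.641,19.3717,20.0346,41.9052,972,
Ifosfamide,64,72,6.4857,166,14.337,9.9968,6.7265,6.6908,13.5206,310,
Cytarabine,88,105,7.6333,234,19.0724,12.9633,8.0409,8.2491,17.2655,444,
Docetaxel,326,403,25.2833,948,67.6692,45.8641,26.9904,28.0924,59.6364,1754,
Paclitaxel,346,429,27.7833,976,73.2084,48.9918,29.2723,30.5924,65.099,1834,
Valrubicin,278,338,22.5714,776,58.8312,39.7812,23.9268,24.7951,52.4217,1452,
Mitomycin C,142,185,10.7571,408,29.6906,19.1994,11.3403,11.977,25.9298,778,
Erdafitinib,172,201,15.4667,438,38.2298,25.6223,15.9611,16.6264,35.0392,840,
Gemcitabine,96,116,7.8381,272,20.1644,13.8365,8.3742,8.5829,17.9789,504,
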