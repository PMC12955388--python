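ACET01	acetate production (pyruvate route)
K00169,K00170
K00625
K00925
//
PROP01	propionate production (succinate route)
K01847
K05606
K03416
K01026
//
BUTY01	butyrate production (acetyl-CoA route)
K00626
K00023,K00074
K01715
K01034,K01035
//
BUTY02	butyrate kinase route
K00929
K00634
//
LACT01	lactate utilisation to SCFA precursors
K00016
K01652
K00656
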