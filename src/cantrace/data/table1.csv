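species,ocean,fao_area,specimen,level,fragment
YFT,AO,FAO34,1,L1,AB
YFT,AO,FAO34,1,L2,AB
YFT,AO,FAO34,1,L3,AB
YFT,AO,FAO34,1,L4O,B
YFT,AO,FAO34,1,L4B,B
YFT,AO,FAO34,2,L1,AB
YFT,AO,FAO34,2,L2,AB
YFT,AO,FAO34,2,L3,AB
YFT,AO,FAO34,2,L4O,B
YFT,AO,FAO34,2,L4B,B
YFT,AO,FAO34,3,L1,AB
YFT,AO,FAO34,3,L2,AB
YFT,AO,FAO34,3,L3,na
YFT,AO,FAO34,3,L4O,B
YFT,AO,FAO34,3,L4B,B
YFT,IO,FAO51,1,L1,AB
YFT,IO,FAO51,1,L2,AB
YFT,IO,FAO51,1,L3,AB
YFT,IO,FAO51,1,L4O,B
YFT,IO,FAO51,1,L4B,B
YFT,IO,FAO51,2,L1,AB
YFT,IO,FAO51,2,L2,AB
YFT,IO,FAO51,2,L3,AB
YFT,IO,FAO51,2,L4O,B
YFT,IO,FAO51,2,L4B,B
YFT,IO,FAO51,3,L1,AB
YFT,IO,FAO51,3,L2,AB
YFT,IO,FAO51,3,L3,AB
YFT,IO,FAO51,3,L4O,B
YFT,IO,FAO51,3,L4B,B
YFT,EPO,FAO87,1,L1,AB
YFT,EPO,FAO87,1,L2,AB
YFT,EPO,FAO87,1,L3,AB
YFT,EPO,FAO87,1,L4O,B
YFT,EPO,FAO87,1,L4B,B
YFT,EPO,FAO87,2,L1,AB
YFT,EPO,FAO87,2,L2,AB
YFT,EPO,FAO87,2,L3,AB
YFT,EPO,FAO87,2,L4O,B
YFT,EPO,FAO87,2,L4B,B
YFT,EPO,FAO87,3,L1,AB
YFT,EPO,FAO87,3,L2,AB
YFT,EPO,FAO87,3,L3,AB
YFT,EPO,FAO87,3,L4O,B
YFT,EPO,FAO87,3,L4B,B
YFT,WCPO,FAO71,1,L1,AB
YFT,WCPO,FAO71,1,L2,AB
YFT,WCPO,FAO71,1,L3,AB
YFT,WCPO,FAO71,1,L4O,B
YFT,WCPO,FAO71,1,L4B,B
YFT,WCPO,FAO71,2,L1,AB
YFT,WCPO,FAO71,2,L2,AB
YFT,WCPO,FAO71,2,L3,AB
YFT,WCPO,FAO71,2,L4O,B
YFT,WCPO,FAO71,2,L4B,B
YFT,WCPO,FAO71,3,L1,AB
YFT,WCPO,FAO71,3,L2,AB
YFT,WCPO,FAO71,3,L3,AB
YFT,WCPO,FAO71,3,L4O,B
YFT,WCPO,FAO71,3,L4B,B
BET,IO,FAO51,1,L1,AB
BET,IO,FAO51,1,L2,AB
BET,IO,FAO51,1,L3,A
BET,IO,FAO51,1,L4O,B
BET,IO,FAO51,1,L4B,B
BET,IO,FAO51,2,L1,AB
BET,IO,FAO51,2,L2,AB
BET,IO,FAO51,2,L3,A
BET,IO,FAO51,2,L4O,B
BET,IO,FAO51,2,L4B,B
BET,IO,FAO51,3,L1,AB
BET,IO,FAO51,3,L2,AB
BET,IO,FAO51,3,L3,A
BET,IO,FAO51,3,L4O,B
BET,IO,FAO51,3,L4B,B
BET,EPO,FAO87,1,L1,AB
BET,EPO,FAO87,1,L2,AB
BET,EPO,FAO87,1,L3,A
BET,EPO,FAO87,1,L4O,B
BET,EPO,FAO87,1,L4B,B
BET,EPO,FAO87,2,L1,AB
BET,EPO,FAO87,2,L2,AB
BET,EPO,FAO87,2,L3,A
BET,EPO,FAO87,2,L4O,B
BET,EPO,FAO87,2,L4B,B
BET,EPO,FAO87,3,L1,AB
BET,EPO,FAO87,3,L2,AB
BET,EPO,FAO87,3,L3,A
BET,EPO,FAO87,3,L4O,B
BET,EPO,FAO87,3,L4B,B
LOT,IO,FAO51,1,L1,AB
LOT,IO,FAO51,1,L2,AB
LOT,IO,FAO51,1,L3,A
LOT,IO,FAO51,1,L4O,B
LOT,IO,FAO51,1,L4B,B
LOT,IO,FAO51,2,L1,AB
LOT,IO,FAO51,2,L2,AB
LOT,IO,FAO51,2,L3,AB
LOT,IO,FAO51,2,L4O,B
LOT,IO,FAO51,2,L4B,B
LOT,IO,FAO51,3,L1,AB
LOT,IO,FAO51,3,L2,AB
LOT,IO,FAO51,3,L3,AB
LOT,IO,FAO51,3,L4O,B
LOT,IO,FAO51,3,L4B,B
SKJ,AO,FAO34,1,L1,AB
SKJ,AO,FAO34,1,L2,AB
SKJ,AO,FAO34,1,L3,AB
SKJ,AO,FAO34,1,L4O,A
SKJ,AO,FAO34,1,L4B,B
SKJ,AO,FAO34,2,L1,AB
SKJ,AO,FAO34,2,L2,AB
SKJ,AO,FAO34,2,L3,AB
SKJ,AO,FAO34,2,L4O,B
SKJ,AO,FAO34,2,L4B,B
SKJ,AO,FAO34,3,L1,AB
SKJ,AO,FAO34,3,L2,AB
SKJ,AO,FAO34,3,L3,na
SKJ,AO,FAO34,3,L4O,B
SKJ,AO,FAO34,3,L4B,B
SKJ,IO,FAO51,1,L1,AB
SKJ,IO,FAO51,1,L2,AB
SKJ,IO,FAO51,1,L3,AB
SKJ,IO,FAO51,1,L4O,B
SKJ,IO,FAO51,1,L4B,B
SKJ,IO,FAO51,2,L1,AB
SKJ,IO,FAO51,2,L2,AB
SKJ,IO,FAO51,2,L3,AB
SKJ,IO,FAO51,2,L4O,B
SKJ,IO,FAO51,2,L4B,na
SKJ,IO,FAO51,3,L1,AB
SKJ,IO,FAO51,3,L2,AB
SKJ,IO,FAO51,3,L3,AB
SKJ,IO,FAO51,3,L4O,B
SKJ,IO,FAO51,3,L4B,B
SKJ,EPO,FAO87,1,L1,AB
SKJ,EPO,FAO87,1,L2,AB
SKJ,EPO,FAO87,1,L3,AB
SKJ,EPO,FAO87,1,L4O,B
SKJ,EPO,FAO87,1,L4B,B
SKJ,EPO,FAO87,2,L1,AB
SKJ,EPO,FAO87,2,L2,AB
SKJ,EPO,FAO87,2,L3,AB
SKJ,EPO,FAO87,2,L4O,B
SKJ,EPO,FAO87,2,L4B,B
SKJ,EPO,FAO87,3,L1,AB
SKJ,EPO,FAO87,3,L2,AB
SKJ,EPO,FAO87,3,L3,AB
SKJ,EPO,FAO87,3,L4O,B
SKJ,EPO,FAO87,3,L4B,B
SKJ,WCPO,FAO71,1,L1,AB
SKJ,WCPO,FAO71,1,L2,AB
SKJ,WCPO,FAO71,1,L3,AB
SKJ,WCPO,FAO71,1,L4O,B
SKJ,WCPO,FAO71,1,L4B,B
SKJ,WCPO,FAO71,2,L1,AB
SKJ,WCPO,FAO71,2,L2,AB
SKJ,WCPO,FAO71,2,L3,AB
SKJ,WCPO,FAO71,2,L4O,B
SKJ,WCPO,FAO71,2,L4B,B
SKJ,WCPO,FAO71,3,L1,AB
SKJ,WCPO,FAO71,3,L2,AB
SKJ,WCPO,FAO71,3,L3,AB
SKJ,WCPO,FAO71,3,L4O,B
SKJ,WCPO,FAO71,3,L4B,B
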