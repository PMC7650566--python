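level,species,ocean,sample_id,fragment,identification,similarity,flagged
L2,LOT,IO,LOT-IO-L2-3,AB,T. thynnus;T. albacares,98.73,0
L3,LOT,IO,LOT-IO-L3-2,AB,T. thynnus;T. albacares,98.73,0
L3,LOT,IO,LOT-IO-L3-3,AB,T. thynnus;T. albacares,98.73,0
L3,SKJ,EPO,SKJ-EPO-L3-2,AB,K. pelamis,96.19,1
L4O,LOT,IO,LOT-IO-L4O-1,B,T. obesus,98.17,0
L4O,YFT,AO,YFT-AO-L4O-1,B,T. obesus,98.17,0
L4O,YFT,AO,YFT-AO-L4O-2,B,K. pelamis,100.00,0
L4O,YFT,IO,YFT-IO-L4O-1,B,K. pelamis,98.17,0
L4O,SKJ,AO,SKJ-AO-L4O-2,B,K. pelamis,97.25,1
L4O,SKJ,EPO,SKJ-EPO-L4O-1,B,T. obesus,98.17,0
L4O,SKJ,EPO,SKJ-EPO-L4O-2,B,T. obesus,98.17,0
L4O,SKJ,IO,SKJ-IO-L4O-1,B,T. obesus,98.17,0
L4O,SKJ,IO,SKJ-IO-L4O-2,B,T. obesus,98.17,0
L4O,SKJ,WCPO,SKJ-WCPO-L4O-1,B,T. obesus,98.17,0
L4B,BET,EPO,BET-EPO-L4B-3,B,K. pelamis,100.00,0
L4B,LOT,IO,LOT-IO-L4B-1,B,T. obesus,98.17,0
L4B,LOT,IO,LOT-IO-L4B-2,B,T. obesus,98.17,0
L4B,YFT,AO,YFT-AO-L4B-1,B,K. pelamis,100.00,0
L4B,YFT,AO,YFT-AO-L4B-2,B,K. pelamis,100.00,0
L4B,YFT,AO,YFT-AO-L4B-3,B,K. pelamis,100.00,0
L4B,YFT,EPO,YFT-EPO-L4B-1,B,K. pelamis;T. albacares;T. obesus,96.33,0
L4B,YFT,EPO,YFT-EPO-L4B-3,B,T. albacares,97.25,1
L4B,YFT,EPO,YFT-EPO-L4B-2,B,K. pelamis,99.08,0
L4B,YFT,IO,YFT-IO-L4B-2,B,T. albacares;T. obesus,97.25,0
L4B,YFT,IO,YFT-IO-L4B-3,B,K. pelamis,99.08,0
L4B,YFT,WCPO,YFT-WCPO-L4B-1,B,K. pelamis,99.08,0
L4B,YFT,WCPO,YFT-WCPO-L4B-3,B,T. albacares;T. obesus,97.25,0
L4B,SKJ,AO,SKJ-AO-L4B-1,B,T. obesus,98.17,0
L4B,SKJ,AO,SKJ-AO-L4B-2,B,T. obesus,98.17,0
L4B,SKJ,EPO,SKJ-EPO-L4B-1,B,T. obesus,98.17,0
L4B,SKJ,EPO,SKJ-EPO-L4B-2,B,T. obesus,98.17,0
L4B,SKJ,IO,SKJ-IO-L4B-1,B,K. pelamis,97.25,1
L4B,SKJ,WCPO,SKJ-WCPO-L4B-1,B,T. obesus,98.17,0
L4B,SKJ,WCPO,SKJ-WCPO-L4B-2,B,T. obesus,98.17,0
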