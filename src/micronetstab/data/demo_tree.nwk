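((((((((ASV01:3.064800,ASV07:0.486648):0.267168,ASV56:0.060114):0.232470,ASV17:0.173244):2.742318,(ASV02:0.743496,(ASV26:0.003206,ASV41:0.313837):1.796763):1.048112):0.523212,(((ASV25:0.245755,ASV27:2.971325):1.769688,ASV32:3.100727):2.156952,(ASV30:0.858660,ASV53:1.319974):0.886234):0.520995):2.012660,((ASV03:0.295493,(ASV37:0.059937,ASV57:0.335354):1.258649):1.982405,ASV38:1.730408):0.905635):0.488112,((((((((ASV08:1.122408,ASV60:0.045797):0.962740,ASV31:0.703781):1.355191,ASV49:2.727457):0.642716,ASV12:0.913132):0.565348,ASV10:2.262314):0.266550,ASV45:0.809981):0.077797,ASV16:0.802680):0.539131,(((((ASV09:0.814964,ASV55:1.016220):0.231063,ASV14:0.599710):1.366746,ASV19:0.968427):1.167267,(ASV20:0.831664,ASV24:3.022672):0.275941):2.072031,(((((ASV11:0.136500,(ASV33:0.385376,ASV42:2.159717):0.225283):0.229407,((ASV18:0.868808,ASV28:0.609300):3.230124,(ASV35:1.214054,ASV51:0.136919):1.694996):0.176609):4.733292,(ASV15:0.400482,ASV52:0.107136):0.124445):0.457221,((ASV21:0.012756,(ASV44:1.737303,ASV54:1.336629):0.073358):1.715111,(ASV29:3.790861,ASV59:0.071407):0.435339):0.818172):0.669057,ASV47:1.433437):1.017819):0.560497):1.253183):4.117805,((((ASV04:1.150441,(ASV13:0.312865,ASV46:1.118897):0.094758):0.686861,(((ASV06:0.089391,ASV22:0.299257):1.919498,ASV39:0.092167):2.445273,ASV43:1.356820):0.114256):2.560697,(ASV05:0.331261,(ASV23:3.467155,(ASV48:0.493584,ASV58:1.087257):0.087646):1.862618):0.935170):0.325491,(ASV34:4.111315,((ASV36:0.324539,ASV50:2.271638):0.832742,ASV40:0.310687):0.907588):0.552808):0.286782);
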