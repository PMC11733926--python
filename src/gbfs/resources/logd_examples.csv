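formula,smiles,logd_expt,logd_pred,pred_minus_expt,pct_diff
C8H16N4S,CC(C)N(C(C)C)c1nnc(N)s1,-0.59065,-0.58704,0.00361,0.6
C19H23FN4O2,Cc1ccc(COC(=O)N2CC[C@H](CNc3ncccn3)[C@H](F)C2)cc1,0.84776,0.85311,0.00535,0.6
C9H13N3O,CC(C)NNC(=O)c1ccncc1,-1.56074,-1.54842,0.01233,0.8
C18H16FNO6S2,Cc1c(CC(=O)O)c2cc(F)ccc2n1S(=O)(=O)c3ccc(cc3)S(=O)(=O)C,-2.20469,-2.22211,-0.01743,-0.8
C28H26F3N3O7,CC(C)C(NC(=O)CN1C(=O)C(=CC=C1c2ccccc2)NC(=O)OCc3ccc(cc3)C(=O)O)C(=O)C(F)(F)F,-1.13424,-1.12462,0.00961,0.8
C26H23N5O,C[C@@H](NC1=CC(=O)CC1)c2ccc(Nc3ncc4cc(ccc4n3)c5ccncc5)cc2,0.83940,0.83187,-0.00753,-0.9
C15H18N4O2S2,NC(=O)Nc1sc(cc1C(=O)N[C@H]2CCCNC2)c3ccsc3,-0.95025,-0.95886,-0.00861,-0.9
C21H18ClN5O4,CN(C)C(=O)Nc1ccc(CN2NC(=O)C3=C(C2=O)C(=O)c4ccc(Cl)cc4N3)cc1,-0.91680,-0.90843,0.00837,0.9
C25H26ClN7O3,COc1cc(ccc1Nc2ncc(Cl)c(n2)c3cnc4cc(CO)ccn34)N5CCN(CC5)C(=O)C,0.75577,0.76341,0.00764,1.0
C10H14N2,CN1CCCC1c2cccnc2,-1.41858,-1.43342,-0.01485,-1.0
C15H22FN3O4S,CC(C)(CS(=O)(=O)N1CCN(CC1)c2ccc(F)cc2)N(O)C=O,-0.94189,-0.95268,-0.01079,-1.1
C24H29F3N2O3S,CCN(C1CCN(Cc2ccc(cc2)C(F)(F)F)CC1)C(=O)Cc3ccc(cc3)S(=O)(=O)C,0.58852,0.58044,-0.00807,-1.4
C23H29N3O5S,CN(CCNC[C@H](O)c1ccc(O)c2NC(=O)Sc12)C(=O)CCOCCc3ccccc3,-0.82481,-0.83644,-0.01162,-1.4
C25H28F3N3O2,COc1ccc2c(C)cc(N[C@H]3CCC[C@@H](C3)NCc4cccc(OC(F)(F)F)c4)nc2c1,1.18228,1.16486,-0.01742,-1.5
C24H29Cl2N3O5S,COc1ccc(cc1)S(=O)(=O)NC(=O)N2CCC(CC2)N3CCC(CC3)Oc4ccc(Cl)c(Cl)c4,-0.67428,-0.68564,-0.01136,-1.7
C25H30N6O2,CN(c1ccccc1)c2ccnc(Nc3cc(cc(c3)N4CCOCC4)N5CCOCC5)n2,1.06520,1.04686,-0.01834,-1.7
C15H17F4N5O4,C[C@H]1O[C@H]([C@H](O)[C@@H]1O)n2cnc3c(N)nc(OCC4CC(F)(F)C4(F)F)nc23,-0.64919,-0.63778,0.01141,1.8
C24H23Cl2N3O4,OC(=O)[C@H](Cc1cccc(OCCCNc2ccccn2)c1)NC(=O)c3c(Cl)cccc3Cl,-1.70291,-1.73467,-0.03176,-1.9
C22H23F5N6O3S,OC[C@H]1C[C@H]([C@H](O)[C@@H]1O)n2nnc3c(N[C@@H]4C[C@H]4c5ccc(F)c(F)c5)nc(SCCC(F)(F)F)nc23,1.50007,1.53064,0.03057,2.0
C18H16ClNO4S2,Cc1c(Sc2ccc(Cl)cc2)c3cc(ccc3n1CC(=O)O)S(=O)(=O)C,-1.38512,-1.35537,0.02975,2.1
C25H27N5O4,O[C@@H]1CN(CCN2C(=O)C=Cc3ccc(cc23)C#N)CC[C@@H]1NCc4cc5OCCOc5cn4,-1.45203,-1.41925,0.03277,2.3
C8H8N4O,NNC1=Nc2ccccc2NC1=O,-1.46875,-1.43553,0.03323,2.3
C24H25N3O3,COc1ccc(cc1)C(=O)Nc2cc(NC(=O)c3cccc(c3)N(C)C)ccc2C,0.81431,0.79583,-0.01849,-2.3
C25H31N5O3,C[C@@H]1CN(CCN1C(=O)[C@@H]2CCCC[C@H]2C(=O)NC3(CC3)C#N)c4ccc5c(C)noc5c4,0.39617,0.38714,-0.00902,-2.3
C26H23F2N3O3,C[C@H](NC(=O)Cc1cc(F)cc(F)c1)C(=O)NC2C(=O)N(C)c3ccccc3c4ccccc24,1.17392,1.14022,-0.03370,-2.9
C22H27ClN2O5S,C[C@H]1CN(Cc2cc(Cl)ccc2OC(C)(C)C(=O)O)CCN1S(=O)(=O)c3ccccc3,-1.38512,-1.42671,-0.04158,-3.0
C16H13F3O4,COc1ccc(cc1)c2cc(ccc2OCC(=O)O)C(F)(F)F,-1.59420,-1.64238,-0.04818,-3.0
C13H18ClNO2,C[C@@H]1NC(C)(C)CO[C@@]1(O)c2cccc(Cl)c2,-0.42339,-0.41045,0.01294,3.1
C11H12F3N5,FC(F)(F)c1nnc2ccc(nn12)N3CCCCC3,0.67214,0.64994,-0.02220,-3.3
C19H15ClN4O3,CCC(N1NC(=O)c2nc3cc(Cl)ccc3c(O)c2C1=O)c4cccnc4,-1.25132,-1.20065,0.05067,4.0
C20H21FN2O,CN(C)CCCC1(OCc2cc(ccc12)C#N)c3ccc(F)cc3,-0.53211,-0.55394,-0.02183,-4.1
C20H19ClN4O5,COc1cc(Nc2cc(Nc3c(Cl)ccc4OCOc34)ncn2)cc(OC)c1OC,0.73068,0.76155,0.03086,4.2
C13H9FN2,Fc1ccc(cc1)c2cn3ccccc3n2,0.75577,0.78804,0.03227,4.3
C23H25ClN4O2S,Cc1sc2c(C(=N[C@@H](CC(=O)OC(C)(C)C)c3nnc(C)n23)c4ccc(Cl)cc4)c1C,1.35790,1.41848,0.06058,4.5
C15H16Cl2N4O3S,Cc1[nH]c(C(=O)NC2CCN(CC2)c3nc(cs3)C(=O)O)c(Cl)c1Cl,-1.71964,-1.80957,-0.08993,-5.2
C6H11NO,O=C1CCCCCN1,-1.90362,-2.00360,-0.09997,-5.3
C25H24F3N3O5,CC1=CN([C@H]2CCCN(Cc3ccc(C(=O)O)c(Oc4cccc(c4)C(F)(F)F)c3)C2)C(=O)NC1=O,-2.15451,-2.04005,0.11446,5.3
C31H36ClN3O5,CC1=CN([C@H]2CCCN(C2)[C@H](CC3CCCCC3)c4ccc(C(=O)O)c(Oc5cccc(Cl)c5)c4)C(=O)NC1=O,-0.30631,-0.29003,0.01628,5.3
C23H25BrN4O,CO[C@@H]1CC[C@@]2(CC1)Cc3ccc(cc3C24N=C(C)C(=N4)N)c5cncc(Br)c5,1.00666,0.95149,-0.05516,-5.5
C11H20N2O2,CC(C)(C)C(=O)N[C@H]1CCCCNC1=O,-1.35167,-1.26705,0.08462,6.3
C26H24N2O3S,CC[C@H](NC(=O)c1c(c(nc2ccccc12)c3ccccc3)S(=O)(=O)C)c4ccccc4,0.81431,0.86580,0.05149,6.3
C17H17N3O2,COc1cc2ncnc(NCc3ccccc3)c2cc1OC,0.91467,0.97275,0.05808,6.3
C20H21F3N2O5S,OC(=O)COc1ccc(cc1CN2CCN(CC2)S(=O)(=O)c3ccccc3)C(F)(F)F,-1.50220,-1.59854,-0.09634,-6.4
C15H11FN4O2,OC(=O)c1ccc(cc1)c2nnn(Cc3ccccc3F)n2,-1.58583,-1.68813,-0.10230,-6.5
C24H22N4O2,COc1ccc(Nc2cc(Oc3cc(C)c(C)nc3c4ccccn4)ccn2)cc1,1.09865,1.01593,-0.08272,-7.5
C16H14ClFO5S,CCS(=O)(=O)c1ccc(c(F)c1)c2cc(Cl)ccc2OCC(=O)O,-2.60610,-2.40706,0.19905,7.6
C22H28ClN3O3S2,O[C@@H](CNCCCSCCNCCc1cccc(Cl)c1)c2ccc(O)c3NC(=O)Sc23,-0.95025,-1.02418,-0.07393,-7.8
C21H25N3O2S,O=S(=O)(NCC(N1CCCCCC1)c2ccccc2)c3ccc(cc3)C#N,0.55506,0.51115,-0.04392,-7.9
C21H25ClFN7O2,C[C@H](Nc1nc(NC[C@@H](O)CO)c(Cl)c(Nc2cc([nH]n2)C3CC3)n1)c4ccc(F)cc4,0.99830,0.91922,-0.07908,-7.9
C16H18N2,CN1C[C@@H](c2ccccc2)c3cccc(N)c3C1,-0.07215,-0.07852,-0.00637,-8.8
C7H8N2O,CC(=O)Nc1ccccn1,-1.41858,-1.54491,-0.12633,-8.9
C25H29F3N2O2S2,CC(C)CN1C(=O)N(C)C(=O)c2c(SC3CCCCC3)c(Cc4ccccc4C(F)(F)F)sc12,1.62551,1.77093,0.14542,8.9
C22H25F3N2O4S,CC(C)Oc1ccc(cc1C(=O)N2CCN(CC2)c3ccc(cc3)C(F)(F)F)S(=O)(=O)C,0.94812,1.03297,0.08485,8.9
C20H15F3N4O3,NC1C2CN(CC12)c3nc4N(C=C(C(=O)O)C(=O)c4cc3F)c5ccc(F)cc5F,-1.58583,-1.44289,0.14294,9.0
C18H15F2N3O3,COc1cc2ncc(C(=O)N)c(Nc3ccc(F)cc3F)c2cc1OC,0.63033,0.56239,-0.06794,-10.8
C21H27N3O3S,CCCSc1c(cnn1c2ccc(cc2)C(=O)O)C(=O)N(C)C3CCCCC3,-1.34331,-1.19841,0.14490,10.8
C27H34N6O2,CN(c1ccnc(Nc2cc(cc(c2)N3CCOCC3)N4CCCC4)n1)c5cc(CO)ccc5C,1.34117,1.48598,0.14481,10.8
C18H20Cl2N2O5S,CNC(=O)OC[C@@H](C)N(c1cc(Cl)ccc1CO)S(=O)(=O)c2ccc(Cl)cc2,0.67214,0.59870,-0.07344,-10.9
C17H17N3O2,COc1cc2ncnc(Nc3cccc(C)c3)c2cc1OC,1.09029,0.97053,-0.11976,-11.0
C20H20ClNO2,Cc1ccc(cc1)C(=O)N2CCC(CC2)C(=O)c3ccc(Cl)cc3,1.33281,1.17617,-0.15664,-11.8
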