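step,method,salt,mass_mg
1,simplex,Ca(NO3)2·4H2O,1983
1,simplex,KH2PO4,0
1,simplex,NH4H2PO4,223.8
1,simplex,KNO3,0
1,simplex,NH4NO3,0
1,simplex,MgSO4·7H2O,1618.4
1,simplex,K2SO4,853.2
1,decision_tree,Ca(NO3)2·4H2O,1983
1,decision_tree,KH2PO4,81.8
1,decision_tree,NH4H2PO4,152.5
1,decision_tree,KNO3,0
1,decision_tree,NH4NO3,0
1,decision_tree,MgSO4·7H2O,1618.4
1,decision_tree,K2SO4,541.5
2,simplex,Ca(NO3)2·4H2O,3946.7
2,simplex,KH2PO4,0
2,simplex,NH4H2PO4,337.5
2,simplex,KNO3,0
2,simplex,NH4NO3,0
2,simplex,MgSO4·7H2O,557.1
2,simplex,K2SO4,2928.4
2,decision_tree,Ca(NO3)2·4H2O,3946.7
2,decision_tree,KH2PO4,99.9
2,decision_tree,NH4H2PO4,207.9
2,decision_tree,KNO3,0
2,decision_tree,NH4NO3,0
2,decision_tree,MgSO4·7H2O,557.1
2,decision_tree,K2SO4,2428.8
3,simplex,Ca(NO3)2·4H2O,0
3,simplex,KH2PO4,1626.5
3,simplex,NH4H2PO4,0
3,simplex,KNO3,4565.6
3,simplex,NH4NO3,1611.6
3,simplex,MgSO4·7H2O,842.8
3,simplex,K2SO4,0
3,decision_tree,Ca(NO3)2·4H2O,0
3,decision_tree,KH2PO4,0
3,decision_tree,NH4H2PO4,21.3
3,decision_tree,KNO3,4778.8
3,decision_tree,NH4NO3,1142.8
3,decision_tree,MgSO4·7H2O,842.8
3,decision_tree,K2SO4,0
4,simplex,Ca(NO3)2·4H2O,5443.2
4,simplex,KH2PO4,0
4,simplex,NH4H2PO4,699.1
4,simplex,KNO3,0
4,simplex,NH4NO3,0
4,simplex,MgSO4·7H2O,1971.8
4,simplex,K2SO4,1353.1
4,decision_tree,Ca(NO3)2·4H2O,5443.2
4,decision_tree,KH2PO4,89.2
4,decision_tree,NH4H2PO4,339.7
4,decision_tree,KNO3,0
4,decision_tree,NH4NO3,0
4,decision_tree,MgSO4·7H2O,1971.8
4,decision_tree,K2SO4,0
5,simplex,Ca(NO3)2·4H2O,3412.9
5,simplex,KH2PO4,901.2
5,simplex,NH4H2PO4,0
5,simplex,KNO3,2482.5
5,simplex,NH4NO3,870.7
5,simplex,MgSO4·7H2O,1066.7
5,simplex,K2SO4,474.2
5,decision_tree,Ca(NO3)2·4H2O,3412.9
5,decision_tree,KH2PO4,0
5,decision_tree,NH4H2PO4,252
5,decision_tree,KNO3,3582.3
5,decision_tree,NH4NO3,0
5,decision_tree,MgSO4·7H2O,1066.7
5,decision_tree,K2SO4,103.1
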