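id,name,smiles,series,sulfur_state,logd_exp,pka_exp
1,2-(methylthio)pyridine,CSc1ccccn1,methyl,thioether,1.69,3.69
2,2-((difluoromethyl)thio)pyridine,FC(F)Sc1ccccn1,methyl,thioether,1.95,
3,2-((trifluoromethyl)thio)pyridine,FC(F)(F)Sc1ccccn1,methyl,thioether,2.13,0.97
4,"2-((1,1-difluoroethyl)thio)pyridine",CC(F)(F)Sc1ccccn1,ethyl,thioether,1.82,
5,2-(ethylthio)pyridine,CCSc1ccccn1,ethyl,thioether,2.26,3.68
6,"2-((2,2-difluoroethyl)thio)pyridine",FC(F)CSc1ccccn1,ethyl,thioether,2.26,2.43
7,"2-((1,1,2,2-tetrafluoroethyl)thio)pyridine",FC(F)C(F)(F)Sc1ccccn1,ethyl,thioether,2.27,
8,"2-((2,2,2-trifluoroethyl)thio)pyridine",FC(F)(F)CSc1ccccn1,ethyl,thioether,2.71,1.49
9,2-((perfluoroethyl)thio)pyridine,FC(F)(F)C(F)(F)Sc1ccccn1,ethyl,thioether,2.76,2.05
10,2-(methylsulfonyl)pyridine,CS(=O)(=O)c1ccccn1,methyl,sulfone,,
11,2-((fluoromethyl)sulfonyl)pyridine,FCS(=O)(=O)c1ccccn1,methyl,sulfone,,
12,2-((difluoromethyl)sulfonyl)pyridine,FC(F)S(=O)(=O)c1ccccn1,methyl,sulfone,0.55,
13,2-((trifluoromethyl)sulfonyl)pyridine,FC(F)(F)S(=O)(=O)c1ccccn1,methyl,sulfone,1.43,
14,2-((2-fluoroethyl)sulfonyl)pyridine,FCCS(=O)(=O)c1ccccn1,ethyl,sulfone,-0.21,
15,2-(ethylsulfonyl)pyridine,CCS(=O)(=O)c1ccccn1,ethyl,sulfone,-0.07,
16,"2-((2,2-difluoroethyl)sulfonyl)pyridine",FC(F)CS(=O)(=O)c1ccccn1,ethyl,sulfone,0.31,
17,"2-((1,1-difluoroethyl)sulfonyl)pyridine",CC(F)(F)S(=O)(=O)c1ccccn1,ethyl,sulfone,0.79,
18,"2-((2,2,2-trifluoroethyl)sulfonyl)pyridine",FC(F)(F)CS(=O)(=O)c1ccccn1,ethyl,sulfone,0.81,
19,"2-((1,1,2,2-tetrafluoroethyl)sulfonyl)pyridine",FC(F)C(F)(F)S(=O)(=O)c1ccccn1,ethyl,sulfone,,
20,2-((perfluoroethyl)sulfonyl)pyridine,FC(F)(F)C(F)(F)S(=O)(=O)c1ccccn1,ethyl,sulfone,,
21,2-((fluoromethyl)thio)pyridine,FCSc1ccccn1,methyl,thioether,,2.43
22,2-((2-fluoroethyl)thio)pyridine,FCCSc1ccccn1,ethyl,thioether,,3.08
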