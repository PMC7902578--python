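compound,group,mrl_mg_kg,analytical_conc_ug_ml,quant_precursor,quant_product,quant_ce,qual_precursor,qual_product,qual_ce,supplier
Alachlor,Alachlor,0.05,0.05,188,160,8,188,132,18,W
Aldrin,Aldrin and dieldrin,0.05,0.05,293,220,24,293,258,12,D
Dieldrin,Aldrin and dieldrin,0.05,0.05,263,193,28,277,241,8,A
Azinphos-ethyl,Azinphos-ethyl,0.1,0.1,160,132,2,132,77,14,D
Azinphos-methyl,Azinphos-methyl,1,1,160,132,2,132,77,14,W
Bromophos-ethyl,Bromophos-ethyl,0.05,0.05,359,331,6,303,239,22,D
Bromophos-methyl,Bromophos-methyl,0.05,0.05,331,316,18,329,314,18,D
Bromopropylate,Bromopropylate,3,3,341,183,18,341,185,18,K
cis-Chlordane,Chlordane,0.05,0.05,373,266,22,375,266,22,D
trans-Chlordane,Chlordane,0.05,0.05,373,266,22,375,266,22,D
Oxychlordane,Chlordane,0.05,0.05,389,353,6,387,323,14,A
cis-Chlorfenvinphos,Chlorfenvinphos,0.5,0.5,267,159,16,323,267,14,W
trans-Chlorfenvinphos,Chlorfenvinphos,0.5,0.5,267,159,16,323,267,14,H
Chlorpyriphos-ethyl,Chlorpyriphos-ethyl,0.2,0.2,314,258,14,286,258,6,W
Chlorpyriphos-methyl,Chlorpyriphos-methyl,0.1,0.1,286,93,24,288,93,24,W
Chlorthal-dimethyl,Chlorthal-dimethyl,0.01,0.01,301,223,26,301,273,16,D
Cyfluthrin,Cyfluthrin,0.1,0.1,226,206,14,226,199,6,D
Cyhalothrin,Cyhalothrin,1,1,208,181,6,197,141,14,D
Cypermethrin,Cypermethrin,1,1,181,152,26,209,116,14,W
"o,p'-DDE",DDT,1,1,246,176,28,318,248,22,A
"p,p'-DDE",DDT,1,1,246,176,28,318,248,22,W
"o,p'-DDD",DDT,1,1,235,165,24,237,165,24,D
"p,p'-DDD",DDT,1,1,235,165,24,237,165,24,W
"o,p'-DDT",DDT,1,1,235,165,24,237,165,24,D
"p,p'-DDT",DDT,1,1,235,165,24,237,165,24,W
Deltamethrin,Deltamethrin,0.5,0.5,253,93,18,253,174,6,W
Diazinon,Diazinon,0.5,0.5,304,179,8,179,137,20,W
Dicofol,Dicofol,0.5,0.5,250,215,4,252,141,12,D
alpha-Endosulfan,Endosulfan,3,3,265,194,8,339,267,4,W
beta-Endosulfan,Endosulfan,3,3,265,194,10,339,267,4,D
Endosulfan-sulfate,Endosulfan,3,3,272,237,14,387,253,10,D
Endrin,Endrin,0.05,0.05,281,245,10,281,209,22,D
Ethion,Ethion,2,2,231,175,12,231,203,6,W
Etrimphos,Etrimphos,0.05,0.05,292,181,6,292,153,22,D
Fenchlorphos,Fenchlorphos,0.1,0.1,287,272,16,285,240,28,D
Fenchlorphos oxon,Fenchlorphos,0.1,0.1,269,254,18,269,224,28,D
Fenitrothion,Fenitrothion,0.5,0.5,277,260,4,277,109,18,W
Fenpropathrin,Fenpropathrin,0.03,0.03,265,210,10,265,89,28,W
Fensulfothion,Fensulfothion,0.05,0.05,308,293,4,293,125,12,W
Fensulfothion oxon,Fensulfothion,0.05,0.05,277,249,6,277,221,12,D
Fensulfothion-oxon-sulfone,Fensulfothion,0.05,0.05,308,182,4,293,229,4,D
Fensulfothion-sulfone,Fensulfothion,0.05,0.05,324,170,4,296,188,8,D
Fenthion,Fenthion,0.05,0.05,278,109,20,278,125,20,D
Fenthion oxon,Fenthion,0.05,0.05,262,247,10,262,217,16,W
Fenthion-oxon-sulfone,Fenthion,0.05,0.05,215,109,12,294,230,6,W
Fenthion-oxon-sulfoxide,Fenthion,0.05,0.05,263,109,16,278,263,6,W
Fenthion-sulfone,Fenthion,0.05,0.05,310,246,4,310,136,18,D
Fenthion sulfoxide,Fenthion,0.05,0.05,294,279,4,279,169,14,D
Fenvalerate,Fenvalerate,1.5,1.5,225,119,18,225,147,8,W
Flucythrinate,Flucythrinate,0.05,0.05,451,199,10,225,147,8,W
Fluvalinate,Fluvalinate,0.05,0.05,250,55,16,250,200,22,W
Fonophos,Fonophos,0.05,0.05,246,109,16,246,137,4,W
Heptachlor,Heptachlor,0.05,0.05,272,237,16,337,266,16,D
cis-Heptachlorepoxide,Heptachlor,0.05,0.05,353,263,14,355,265,16,D
trans-Heptachlorepoxide,Heptachlor,0.05,0.05,353,253,16,355,291,8,D
Hexachlorobenzene,Hexachlorobenzene,0.1,0.1,284,249,22,249,214,16,D
alpha-Hexachlorocyclohexane,Hexachlorocyclohexane,0.3,0.3,219,183,6,181,145,14,D
beta-Hexachlorocyclohexane,Hexachlorocyclohexane,0.3,0.3,219,183,8,181,145,16,D
delta-Hexachlorocyclohexane,Hexachlorocyclohexane,0.3,0.3,219,183,8,181,145,16,D
epsilon-Hexachlorocyclohexane,Hexachlorocyclohexane,0.3,0.3,219,183,8,181,145,14,K
gamma-Hexachlorocyclohexane,Lindane,0.6,0.6,219,183,6,181,145,14,W
Malathion,Malathion and malaoxon,1,1,173,99,14,173,127,4,D
Malaoxon,Malathion and malaoxon,1,1,268,127,6,268,99,12,W
Mecarbam,Mecarbam,0.05,0.05,329,131,14,296,196,6,D
Methacriphos,Methacriphos,0.05,0.05,240,208,2,208,180,4,D
Methidathion,Methidathion,0.2,0.2,145,85,6,145,58,14,D
Methoxychlor,Methoxychlor,0.05,0.05,227,169,28,227,212,16,W
Mirex,Mirex,0.01,0.01,272,237,16,332,297,22,D
Parathion-ethyl,Parathion-ethyl and paraoxon-ethyl,0.5,0.5,291,109,12,291,81,28,W
Paraoxon-ethyl,Parathion-ethyl and paraoxon-ethyl,0.5,0.5,275,99,16,275,149,4,D
Parathion-methyl,Parathion-methyl and paraoxon-methyl,0.2,0.2,263,109,10,246,216,4,W
Paraoxon-methyl,Parathion-methyl and paraoxon-methyl,0.2,0.2,230,200,6,230,136,10,F
Pentachloroanisole,Pentachloroanisole,0.01,0.01,265,237,14,280,237,26,D
cis-Permethrin,Permethrin,1,1,183,168,14,163,127,6,D
trans-Permethrin,Permethrin,1,1,183,168,14,163,127,6,W
Phosalone,Phosalone,0.1,0.1,182,111,16,367,182,6,W
Phosmet,Phosmet,0.05,0.05,160,133,14,317,160,4,W
Pirimiphos-ethyl,Pirimiphos-ethyl,0.05,0.05,318,166,14,333,180,6,D
Pirimiphos-methyl,Pirimiphos-methyl,4,4,290,233,10,305,290,8,D
N-Desethyl-pirimiphos-methyl,Pirimiphos-methyl,4,4,277,168,6,277,262,8,D
Procymidone,Procymidone,0.1,0.1,283,96,10,283,255,10,D
Profenophos,Profenophos,0.1,0.1,339,269,14,339,311,4,W
Prothiophos,Prothiophos,0.05,0.05,267,239,8,309,239,16,W
Quinalphos,Quinalphos,0.05,0.05,298,156,6,270,189,8,D
Quintozene,Quintozene,1,1,295,237,18,295,265,8,W
Pentachloroaniline,Quintozene,1,1,265,194,24,267,194,24,W
Methyl pentachlorophenyl sulfide,Quintozene,1,1,296,263,16,296,246,28,F
s-421,s-421,0.02,0.02,211,79,6,181,85,8,D
Tecnazene,Tecnazene,0.05,0.05,261,203,14,215,179,10,W
Tetradifon,Tetradifon,0.3,0.3,227,199,16,356,159,12,W
Vinclozolin,Vinclozolin,0.4,0.4,285,212,12,212,172,14,D
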