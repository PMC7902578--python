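compound,loq_mg_kg
Alachlor,0.01
Aldrin,0.005
Dieldrin,0.005
Azinphos-ethyl,0.05
Azinphos-methyl,0.2
Bromophos-ethyl,0.005
Bromophos-methyl,0.005
Bromopropylate,0.3
cis-Chlordane,0.005
trans-Chlordane,0.005
Oxychlordane,0.005
cis-Chlorfenvinphos,0.05
trans-Chlorfenvinphos,0.05
Chlorpyriphos-ethyl,0.02
Chlorpyriphos-methyl,0.01
Chlorthal-dimethyl,0.001
Cyfluthrin,0.05
Cyhalothrin,0.2
Cypermethrin,0.2
"o,p'-DDE",0.1
"p,p'-DDE",0.1
"o,p'-DDD",0.1
"p,p'-DDD",0.1
"o,p'-DDT",0.1
"p,p'-DDT",0.1
Deltamethrin,0.5
Diazinon,0.05
Dicofol,0.1
alpha-Endosulfan,0.3
beta-Endosulfan,0.3
Endosulfan-sulfate,0.3
Endrin,0.005
Ethion,0.2
Etrimphos,0.005
Fenchlorphos,0.01
Fenchlorphos oxon,
Fenitrothion,0.05
Fenpropathrin,0.003
Fensulfothion,0.05
Fensulfothion oxon,0.025
Fensulfothion-oxon-sulfone,0.01
Fensulfothion-sulfone,0.005
Fenthion,0.005
Fenthion oxon,0.005
Fenthion-oxon-sulfone,0.01
Fenthion-oxon-sulfoxide,0.025
Fenthion-sulfone,0.005
Fenthion sulfoxide,0.05
Fenvalerate,0.75
Flucythrinate,0.05
Fluvalinate,0.05
Fonophos,0.005
Heptachlor,0.005
cis-Heptachlorepoxide,0.005
trans-Heptachlorepoxide,0.01
Hexachlorobenzene,0.01
alpha-Hexachlorocyclohexane,0.03
beta-Hexachlorocyclohexane,0.03
delta-Hexachlorocyclohexane,0.03
epsilon-Hexachlorocyclohexane,0.03
gamma-Hexachlorocyclohexane,0.06
Malaoxon,0.1
Malathion,0.1
Mecarbam,0.005
Methacriphos,0.005
Methidathion,0.02
Methoxychlor,0.01
Mirex,0.01
Parathion-ethyl,0.1
Paraoxon-ethyl,0.05
Parathion-methyl,0.02
Paraoxon-methyl,
Pentachloroanisole,0.001
cis-Permethrin,0.2
trans-Permethrin,0.1
Phosalone,0.02
Phosmet,0.01
Pirimiphos-ethyl,0.005
Pirimiphos-methyl,0.4
N-Desethyl-pirimiphos-methyl,0.4
Procymidone,0.01
Profenophos,
Prothiophos,0.005
Quinalphos,0.005
Quintozene,0.1
Pentachloroaniline,0.1
Methyl pentachlorophenyl sulfide,0.1
s-421,0.01
Tecnazene,0.005
Tetradifon,0.03
Vinclozolin,0.04
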