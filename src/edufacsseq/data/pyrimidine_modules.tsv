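# Pyrimidine pathway completeness rules.
# One rule per line: name<TAB>groups. Groups are comma-separated; alternative
# KOs within a group are pipe-separated (a group is satisfied by ANY member).
pyrimidine_salvage	K00857,K00943,K00940
pyrimidine_de_novo	K00226|K00254|K17828,K00609,K00610,K00762,K01465,K01591,K01955,K01956
pyrimidine_deoxyribonucleoside	K00525,K00526,K00560,K00940,K00943,K01520
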