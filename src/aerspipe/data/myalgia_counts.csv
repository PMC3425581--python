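drug,primary_count,all_count
rosuvastatin,1641,2019
fluvastatin,103,184
atorvastatin,2751,3667
pravastatin,257,541
simvastatin,1003,1827
lovastatin,67,189
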