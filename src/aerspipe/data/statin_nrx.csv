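drug,nrx
simvastatin,122377000
atorvastatin,105289000
rosuvastatin,35505000
lovastatin,26345000
pravastatin,27843000
fluvastatin,3238000
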