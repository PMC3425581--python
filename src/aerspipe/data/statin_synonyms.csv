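canonical,variant
atorvastatin,atorvastatin
atorvastatin,atorvastatin calcium
atorvastatin,lipitor
atorvastatin,atorvastatina
atorvastatin,atorvastatine
atorvastatin,atorvastatinum
atorvastatin,torvast
atorvastatin,sortis
atorvastatin,atorvastin
atorvastatin,atorvostatin
simvastatin,simvastatin
simvastatin,zocor
simvastatin,simvastatina
simvastatin,simvastatine
simvastatin,simvastatinum
simvastatin,simvahexal
simvastatin,simvastin
simvastatin,simvistatin
lovastatin,lovastatin
lovastatin,mevacor
lovastatin,altoprev
lovastatin,lovastatina
lovastatin,lovastatine
lovastatin,lovostatin
pravastatin,pravastatin
pravastatin,pravastatin sodium
pravastatin,pravachol
pravastatin,pravastatina
pravastatin,pravastatine
pravastatin,pravastatinum
pravastatin,selektine
pravastatin,pravastin
rosuvastatin,rosuvastatin
rosuvastatin,rosuvastatin calcium
rosuvastatin,crestor
rosuvastatin,rosuvastatina
rosuvastatin,rosuvastatine
rosuvastatin,rosuvastatinum
rosuvastatin,rosuvastin
fluvastatin,fluvastatin
fluvastatin,fluvastatin sodium
fluvastatin,lescol
fluvastatin,lescol xl
fluvastatin,fluvastatina
fluvastatin,fluvastatine
fluvastatin,fluvastatinum
fluvastatin,fluvastin
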