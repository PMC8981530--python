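statin,dose_mg,ldl_reduction_pct
atorvastatin,10,37
atorvastatin,20,43
atorvastatin,40,49
atorvastatin,80,55
fluvastatin,20,21
fluvastatin,40,27
fluvastatin,80,33
pravastatin,10,20
pravastatin,20,24
pravastatin,40,29
rosuvastatin,5,38
rosuvastatin,10,43
rosuvastatin,20,48
rosuvastatin,40,53
simvastatin,10,27
simvastatin,20,32
simvastatin,40,37
simvastatin,80,42
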