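biomarker,stage,mode,mean,sd,min,max,units
RMP,calibration,minmax,-86,,-100,-70,mV
APD20,calibration,implausibility,172,29,86,262,ms
APD50,calibration,implausibility,230,39,117,351,ms
APD90,calibration,implausibility,311,49,170,464,ms
Tri9040,calibration,implausibility,135,39,27,261,ms
CTmin,calibration,minmax,0.152,0.03,0,0.242,uM
CTmax,calibration,minmax,1.120,0.128,0.736,1.504,uM
CaTTP,calibration,minmax,,,30,300,ms
CTD50,calibration,minmax,,,55,270,ms
CTD80,calibration,minmax,,,120,465,ms
FTTP,recalibration,minmax,275,21,212,338,ms
FTTr,recalibration,minmax,301,58,127,475,ms
FTD,recalibration,minmax,501,42,375,627,ms
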