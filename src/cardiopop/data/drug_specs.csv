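drug,channel,ic50_uM,hill,eftpc_uM,risk_category
Dofetilide,INa,31.9,0.54,0.002,1
Dofetilide,ICaL,201,1,0.002,1
Dofetilide,IKr,0.013,1.56,0.002,1
Dofetilide,IKs,135,1,0.002,1
Verapamil,INa,32.5,1.33,0.09,0
Verapamil,ICaL,0.2,0.80,0.09,0
Verapamil,IKr,0.25,0.89,0.09,0
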