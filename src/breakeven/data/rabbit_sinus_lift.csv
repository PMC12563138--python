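study,material,time_value,time_unit,new_bone_pct,residual_graft_pct
Lambert 2011,Autogenous,1,week,0.3,22.7
Lambert 2011,Autogenous,5,week,32.7,0.0
Lambert 2011,Bio-Oss,1,week,0.1,42.7
Lambert 2011,Bio-Oss,6,month,16,34.9
Yamada 2025,Bio-Oss,2,week,7.0,47.8
Yamada 2025,Bio-Oss,12,week,34.4,33.1
Yamada 2025,Bio-Oss Collagen,2,week,3.4,41.8
Yamada 2025,Bio-Oss Collagen,12,week,39.4,22.2
Costa 2021,Maxresorb,2,week,2.65,52.05
Costa 2021,Maxresorb,10,week,34.2,37.38
Costa 2021,Maxresorb Inject,2,week,0.08,79.72
Costa 2021,Maxresorb Inject,10,week,23.28,48.63
Iida 2017,Gen-Os,2,week,6.17,35.2
Iida 2017,Gen-Os,8,week,26.72,9.62
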