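kind,t0,duration,DGS,DGF,hr_pct,name
meal,600,,47.6,0.0,,
meal,840,,41.0,0.0,,
meal,1080,,16.3,0.0,,
meal,1260,,16.8,22.9,,
activity,510,60,,,12.0,computer_work
activity,570,30,,,22.0,domestic_light
activity,600,90,,,40.0,walk
activity,690,150,,,15.0,desk_and_domestic
activity,870,90,,,10.0,reading
activity,990,90,,,12.0,computer_work
activity,1080,120,,,40.0,walk
activity,1200,60,,,22.0,domestic_light
activity,1290,149,,,10.0,tv_smartphone
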