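stratum,exposure,proportion,risk
high_activity,0,0.5,0.1
high_activity,1,0.3,0.15
low_activity,0,0.05,0.2
low_activity,1,0.15,0.6
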