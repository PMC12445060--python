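label,start_year,start_month,end_year,end_month,rate_median,rate_p05,rate_p95
Silo 1 actively filled,1952,7,1953,6,1900,200,4200
Silo 2 actively filled,1953,6,1958,9,4900,3100,7600
Before sealing silo domes,1958,9,1979,6,6200,4200,8700
After sealing silo domes,1979,7,1987,12,950,360,1700
Foam insulation of silo airspace,1988,1,1988,12,540,120,1300
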