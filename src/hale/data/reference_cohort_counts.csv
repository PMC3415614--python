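# Published characteristics (counts by sex) of living colorectal-cancer
# survivors, Eindhoven Cancer Registry area, observation window 2005-2009.
variable,level,male,female
age_at_diagnosis,<50,371,312
age_at_diagnosis,50-64,2753,2143
age_at_diagnosis,65-79,3899,3394
age_at_diagnosis,80+,800,1177
age_in_window,50-64,2329,1712
age_in_window,65-79,4127,3423
age_in_window,80+,1367,1891
ses,low,1725,1970
ses,middle,3042,2556
ses,high,2531,1884
ses,institutionalized,257,359
ses,unknown,268,257
site,colon,4731,4875
site,rectum,3092,2151
stage,I,2121,1763
stage,II,2697,2587
stage,III,1875,1784
stage,IV,1130,892
treatment,surgery_only,4321,4525
treatment,surgery_chemo,1174,1027
treatment,surgery_radio_chemo,1729,1250
treatment,other,599,635
comorbidity,0,2353,2239
comorbidity,1plus,4272,3537
comorbidity,unknown,1198,1250
total,all,7823,7026
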