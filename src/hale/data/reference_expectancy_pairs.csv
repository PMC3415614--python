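# Published life expectancy / healthy life expectancy pairs (years) for
# colorectal-cancer survivors (Eindhoven Cancer Registry area, 2005-2009),
# with the percent of remaining life in good health as printed.  Only rows
# whose printed percent is consistent with rounding 100*HLE/LE of the
# printed years are included.
label,stratum,level,age,le_years,hle_years,printed_pct
men_age50,sex,male,50,12.3,9.5,77
women_age50,sex,female,50,13.3,9.9,74
men_age80,sex,male,80,5.5,3.8,69
men_stage_II,stage,II,50,19.2,16.0,83
men_ses_low,ses,low,50,9.3,6.0,65
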