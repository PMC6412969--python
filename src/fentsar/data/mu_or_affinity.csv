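compound_id,name,ic50_nM,sd_nM,chiral
F01,fentanyl,1.23,0.14,0
F02,N-[3-(methyl-phenethylamino)propyl]-N-phenyl propionamide,60.25,3.51,0
F03,benzylfentanyl,489.7,28.6,0
F04,thienylfentanyl,245.5,12.9,0
F05,alpha-methylfentanyl,0.32,0.01,1
F06,beta-hydroxyfentanyl,2.81,0.13,1
F07,"3'',4''-dimethoxyfentanyl",977.2,43.11,0
F08,"3'',4''-dimethoxy-para-trifluoromethylfentanyl",>1000.0,,0
F09,cyclopropylfentanyl,0.77,0.04,0
F10,omega-hydroxyfentanyl,97.7,5.80,0
F11,omega-1-hydroxyfentanyl,489.0,40.59,1
F12,para-fluorofentanyl,0.48,0.03,0
F13,para-trifluoromethylfentanyl,95.5,6.2,0
F14,ohmefentanyl,0.27,0.03,1
F15,carfentanil,0.19,0.01,0
F16,lofentanil,0.21,0.01,0
F17,remifentanil,0.60,0.08,0
F18,norcarfentanil,295.1,1.3,0
F19,alfentanil,38.9,2.8,0
F20,3-methylothiofentanyl,1.10,0.10,1
F21,sufentanil,0.40,0.03,0
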