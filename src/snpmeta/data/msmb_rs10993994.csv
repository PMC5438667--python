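study_id,year,ethnicity,soc,case_cc,case_ct,case_tt,control_cc,control_ct,control_tt,nos
Sjoblom2016,2016,Caucasian,HB,154,160,54,394,396,111,6
Mhatre2015,2015,Asian,PB,9,24,17,5,10,15,7
Shui2014,2014,Caucasian,PB,3289,5168,2030,4102,5245,1677,6
Stott-Miller2013,2013,Caucasian,PB,377,621,241,465,599,168,7
FitzGerald2013,2013,Caucasian,PB,382,633,242,472,608,173,7
Haiman2013,2013,Mixed,PB,314,588,319,359,585,286,6
Ho2012,2012,Caucasian,PB,83,94,65,102,119,43,6
Chang2011,2011,African-American,HB,1553,1904,583,1349,1799,600,7
Xu2010,2010,Asian,PB,57,122,72,71,140,47,6
Chang2009a,2009,Caucasian,PB,963,1354,546,627,810,264,6
Chang2009b,2009,Caucasian,HB,1380,2129,935,1275,1584,491,6
Eeles2008a,2008,Caucasian,HB,543,921,390,815,854,225,6
Eeles2008b,2008,Caucasian,HB,960,1622,686,1204,1618,544,6
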