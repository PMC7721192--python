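tag_year,tag_region,length_class,count
2009,MU1,ALL,3557
2010,MU1,ALL,3782
2011,MU2,ALL,1875
2012,MU1,ALL,2837
2012,MU2,ALL,124
2013,MU1,ALL,219
2013,MU2,ALL,294
2014,MU2,ALL,787
2015,MU2,ALL,219
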