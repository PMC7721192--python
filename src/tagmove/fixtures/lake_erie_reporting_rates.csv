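year,region,rate
2009,MU1,0.29
2010,MU1,0.20
2011,MU1,0.41
2012,MU1,0.50
2013,MU1,0.51
2014,MU1,0.49
2015,MU1,0.52
2009,MU2,0.19
2010,MU2,0.21
2011,MU2,0.38
2012,MU2,0.43
2013,MU2,0.46
2014,MU2,0.44
2015,MU2,0.44
2009,MU3,0.09
2010,MU3,0.14
2011,MU3,0.25
2012,MU3,0.29
2013,MU3,0.32
2014,MU3,0.34
2015,MU3,0.33
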