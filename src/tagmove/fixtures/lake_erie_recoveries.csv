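tag_year,tag_region,length_class,recovery_year,recovery_region,count
2009,MU1,ALL,2009,MU1,40
2009,MU1,ALL,2010,MU1,7
2009,MU1,ALL,2011,MU1,8
2009,MU1,ALL,2012,MU1,2
2009,MU1,ALL,2013,MU1,1
2009,MU1,ALL,2014,MU1,0
2009,MU1,ALL,2015,MU1,0
2009,MU1,ALL,2009,MU2,3
2009,MU1,ALL,2010,MU2,4
2009,MU1,ALL,2011,MU2,5
2009,MU1,ALL,2012,MU2,1
2009,MU1,ALL,2013,MU2,0
2009,MU1,ALL,2014,MU2,0
2009,MU1,ALL,2015,MU2,0
2009,MU1,ALL,2009,MU3,1
2009,MU1,ALL,2010,MU3,1
2009,MU1,ALL,2011,MU3,0
2009,MU1,ALL,2012,MU3,1
2009,MU1,ALL,2013,MU3,0
2009,MU1,ALL,2014,MU3,0
2009,MU1,ALL,2015,MU3,0
2010,MU1,ALL,2010,MU1,9
2010,MU1,ALL,2011,MU1,14
2010,MU1,ALL,2012,MU1,10
2010,MU1,ALL,2013,MU1,2
2010,MU1,ALL,2014,MU1,0
2010,MU1,ALL,2015,MU1,0
2010,MU1,ALL,2010,MU2,5
2010,MU1,ALL,2011,MU2,3
2010,MU1,ALL,2012,MU2,3
2010,MU1,ALL,2013,MU2,0
2010,MU1,ALL,2014,MU2,0
2010,MU1,ALL,2015,MU2,0
2010,MU1,ALL,2010,MU3,1
2010,MU1,ALL,2011,MU3,0
2010,MU1,ALL,2012,MU3,1
2010,MU1,ALL,2013,MU3,0
2010,MU1,ALL,2014,MU3,0
2010,MU1,ALL,2015,MU3,0
2011,MU2,ALL,2011,MU1,0
2011,MU2,ALL,2012,MU1,2
2011,MU2,ALL,2013,MU1,1
2011,MU2,ALL,2014,MU1,2
2011,MU2,ALL,2015,MU1,0
2011,MU2,ALL,2011,MU2,5
2011,MU2,ALL,2012,MU2,11
2011,MU2,ALL,2013,MU2,2
2011,MU2,ALL,2014,MU2,0
2011,MU2,ALL,2015,MU2,0
2011,MU2,ALL,2011,MU3,5
2011,MU2,ALL,2012,MU3,14
2011,MU2,ALL,2013,MU3,3
2011,MU2,ALL,2014,MU3,1
2011,MU2,ALL,2015,MU3,0
2012,MU1,ALL,2012,MU1,28
2012,MU1,ALL,2013,MU1,23
2012,MU1,ALL,2014,MU1,14
2012,MU1,ALL,2015,MU1,3
2012,MU1,ALL,2012,MU2,16
2012,MU1,ALL,2013,MU2,4
2012,MU1,ALL,2014,MU2,2
2012,MU1,ALL,2015,MU2,0
2012,MU1,ALL,2012,MU3,1
2012,MU1,ALL,2013,MU3,1
2012,MU1,ALL,2014,MU3,0
2012,MU1,ALL,2015,MU3,0
2012,MU2,ALL,2012,MU1,0
2012,MU2,ALL,2013,MU1,0
2012,MU2,ALL,2014,MU1,1
2012,MU2,ALL,2015,MU1,0
2012,MU2,ALL,2012,MU2,2
2012,MU2,ALL,2013,MU2,3
2012,MU2,ALL,2014,MU2,0
2012,MU2,ALL,2015,MU2,0
2012,MU2,ALL,2012,MU3,0
2012,MU2,ALL,2013,MU3,0
2012,MU2,ALL,2014,MU3,0
2012,MU2,ALL,2015,MU3,0
2013,MU1,ALL,2013,MU1,5
2013,MU1,ALL,2014,MU1,3
2013,MU1,ALL,2015,MU1,0
2013,MU1,ALL,2013,MU2,0
2013,MU1,ALL,2014,MU2,1
2013,MU1,ALL,2015,MU2,0
2013,MU1,ALL,2013,MU3,0
2013,MU1,ALL,2014,MU3,0
2013,MU1,ALL,2015,MU3,0
2013,MU2,ALL,2013,MU1,0
2013,MU2,ALL,2014,MU1,0
2013,MU2,ALL,2015,MU1,0
2013,MU2,ALL,2013,MU2,4
2013,MU2,ALL,2014,MU2,0
2013,MU2,ALL,2015,MU2,4
2013,MU2,ALL,2013,MU3,6
2013,MU2,ALL,2014,MU3,3
2013,MU2,ALL,2015,MU3,2
2014,MU2,ALL,2014,MU1,1
2014,MU2,ALL,2015,MU1,0
2014,MU2,ALL,2014,MU2,5
2014,MU2,ALL,2015,MU2,4
2014,MU2,ALL,2014,MU3,7
2014,MU2,ALL,2015,MU3,6
2015,MU2,ALL,2015,MU1,0
2015,MU2,ALL,2015,MU2,2
2015,MU2,ALL,2015,MU3,3
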