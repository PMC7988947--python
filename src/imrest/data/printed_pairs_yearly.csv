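sex,year,observed,expected,relative_deviation
male,2004,1990,1881,-5.5
male,2005,2207,2100,-4.8
male,2006,2144,2100,-2.1
male,2007,2262,2123,-6.1
male,2008,2363,2228,-5.7
male,2009,2468,2277,-7.7
male,2010,2370,2390,0.8
male,2011,2437,2381,-2.3
male,2012,2527,2617,3.6
male,2013,2429,3029,24.7
female,2004,1459,1414,-3.1
female,2005,1542,1510,-2.1
female,2006,1510,1580,4.6
female,2007,1672,1575,-5.8
female,2008,1635,1603,-2.0
female,2009,1809,1725,-4.6
female,2010,1739,1809,4.0
female,2011,1788,1716,-4.0
female,2012,1695,1752,3.4
female,2013,1802,1890,4.9
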