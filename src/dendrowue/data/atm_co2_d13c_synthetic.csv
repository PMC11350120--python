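# Synthetic stand-in for the annual atmospheric history used in the iWUE chain.
# co2_ppm: Mauna Loa annual means (widely published values, rounded).
# d13c_atm_permil: smooth monotone (quadratic) approximation of the industrial-era
#   Suess-effect decline in atmospheric d13C (about -7.25 permil in 1965 to
#   -8.46 permil in 2014); NOT an exact copy of any measured atmospheric d13C series.
year,co2_ppm,d13c_atm_permil
1965,320.04,-7.2500
1966,321.37,-7.2603
1967,322.18,-7.2712
1968,323.05,-7.2827
1969,324.62,-7.2948
1970,325.68,-7.3075
1971,326.32,-7.3208
1972,327.46,-7.3347
1973,329.68,-7.3492
1974,330.19,-7.3643
1975,331.12,-7.3800
1976,332.03,-7.3963
1977,333.84,-7.4132
1978,335.41,-7.4307
1979,336.84,-7.4488
1980,338.76,-7.4675
1981,340.12,-7.4868
1982,341.48,-7.5067
1983,343.15,-7.5272
1984,344.85,-7.5483
1985,346.35,-7.5700
1986,347.61,-7.5923
1987,349.31,-7.6152
1988,351.69,-7.6387
1989,353.20,-7.6628
1990,354.45,-7.6875
1991,355.70,-7.7128
1992,356.54,-7.7387
1993,357.21,-7.7652
1994,358.96,-7.7923
1995,360.97,-7.8200
1996,362.74,-7.8483
1997,363.88,-7.8772
1998,366.84,-7.9067
1999,368.54,-7.9368
2000,369.71,-7.9675
2001,371.32,-7.9988
2002,373.45,-8.0307
2003,375.98,-8.0632
2004,377.70,-8.0963
2005,379.98,-8.1300
2006,382.09,-8.1643
2007,384.02,-8.1992
2008,385.83,-8.2347
2009,387.64,-8.2708
2010,390.10,-8.3075
2011,391.85,-8.3448
2012,394.06,-8.3827
2013,396.74,-8.4212
2014,398.81,-8.4603
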