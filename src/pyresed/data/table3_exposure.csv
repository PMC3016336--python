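year,max_tu,precip_nov_dec_cm,precip_annual_cm,bifenthrin_sep_oct_kg,bifenthrin_annual_kg
1990,0.0117,1.72,17.87,0.00,0.00
1991,0.1045,2.4,23.05,0.00,0.00
1992,0.2072,2.52,22.9,0.00,24.05
1993,0.3128,0.89,19.16,0.00,29.41
1994,0.2629,0.71,6.37,0.00,13.66
1995,0.1798,3.73,29.54,1.34,2.77
1996,0.3257,12.12,41.76,0.00,10.42
1997,0.2682,12.3,26.03,0.00,9.65
1998,0.2715,3.96,47.44,0.00,10.24
1999,0.1976,2.24,28.2,0.00,3.15
2000,0.1286,0.65,19.34,8.14,41.10
2001,0.4581,9.2,26.03,0.00,31.93
2002,1.1647,11.44,24.53,13.34,48.73
2003,1.3027,7.23,16.9,18.73,64.19
2004,0.5627,8.49,25.67,1.34,13.52
2005,0.4622,3.92,25.67,6.38,36.93
2006,0.2462,2.8,19.01,9.60,31.01
2007,0.3816,3.47,12.91,4.02,83.24
2008,0.3923,3.26,12.95,1.76,61.13
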