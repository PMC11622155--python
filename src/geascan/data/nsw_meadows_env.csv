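meadow,AvTemp,MaxTemp,TempRange,pHRange,MinpH,MaxSal,AvSal,TurbRange,MinTurb
Wallis Lake,23.39,30.31,13.64,1.69,7.89,41.99,33.46,8.40,0.05
Port Stephens,22.32,28.57,13.57,0.39,7.88,38.96,30.64,6.48,1.10
Lake Macquarie,24.19,28.80,12.82,1.03,7.84,37.22,34.28,31.89,0.02
Brisbane Water,22.90,27.69,12.90,0.90,7.92,36.86,31.13,2.76,0.14
Pittwater,23.41,25.16,4.41,4.54,8.00,35.62,35.08,1.40,0.22
Sydney Harbour,24.40,27.90,6.62,0.74,7.21,25.44,29.77,11.40,0.87
Botany Bay,22.60,31.00,18.03,0.88,7.30,42.70,31.60,10.25,2.34
Port Hacking,24.82,28.73,7.93,0.78,7.52,36.04,28.44,9.77,0.33
Batemans Bay,22.23,28.95,12.45,1.02,7.26,38.84,27.77,17.71,0.70
Wagonga Inlet,21.24,28.75,15.75,0.24,8.04,42.51,31.71,1.36,0.11
Bermagui,20.14,26.16,11.66,0.24,7.67,37.10,34.66,2.21,1.28
Merimbula,20.30,25.85,11.72,0.96,8.06,40.59,30.95,1.81,0.30
Pambula,20.21,26.13,11.45,0.19,7.90,42.38,32.40,2.42,0.55
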