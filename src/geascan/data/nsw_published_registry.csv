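meadow,variable,current,rate,proj_2030,proj_2040,proj_2050,donor_2030,donor_2040,donor_2050
Wallis Lake,AvTemp,23.39,0.2,24.59,26.59,28.59,Port Hacking,NA,NA
Port Stephens,AvTemp,22.32,0.2,23.52,25.52,27.52,Wallis Lake,NA,NA
Lake Macquarie,AvTemp,24.19,0.2,25.39,27.39,29.39,NA,NA,NA
Brisbane Water,AvTemp,22.90,0.2,24.10,26.10,28.10,Lake Macquarie,NA,NA
Pittwater,AvTemp,23.41,0.2,24.61,26.61,28.61,Port Hacking,NA,NA
Sydney Harbour,AvTemp,24.40,0.2,25.60,27.60,29.60,NA,NA,NA
Botany Bay,AvTemp,22.60,0.2,23.80,25.80,27.80,Lake Macquarie,NA,NA
Port Hacking,AvTemp,24.82,0.2,26.02,28.02,30.02,NA,NA,NA
Batemans Bay,AvTemp,22.23,0.2,23.43,25.43,27.43,Pittwater,NA,NA
Wagonga Inlet,AvTemp,21.24,0.2,22.44,24.44,26.44,Botany Bay,Sydney Harbour,NA
Bermagui,AvTemp,20.14,0.2,21.34,23.34,25.34,Batemans Bay,Pittwater,NA
Merimbula,AvTemp,20.30,0.2,21.50,23.50,25.50,Batemans Bay,Pittwater,NA
Pambula,AvTemp,20.21,0.2,21.41,23.41,25.41,Batemans Bay,Pittwater,NA
Wallis Lake,MaxTemp,30.31,0.2,31.51,33.51,35.51,NA,NA,NA
Port Stephens,MaxTemp,28.57,0.2,29.77,31.77,33.77,Wallis Lake,NA,NA
Lake Macquarie,MaxTemp,28.80,0.2,30.00,32.00,34.00,Wallis Lake,NA,NA
Brisbane Water,MaxTemp,27.69,0.2,28.89,30.89,32.89,Batemans Bay,Botany Bay,NA
Pittwater,MaxTemp,25.16,0.2,26.36,28.36,30.36,Brisbane Water,Port Stephens,Botany Bay
Sydney Harbour,MaxTemp,27.90,0.2,29.10,31.10,33.10,Wallis Lake,Botany Bay,NA
Botany Bay,MaxTemp,31.00,0.2,32.20,34.20,36.20,NA,NA,NA
Port Hacking,MaxTemp,28.73,0.2,29.93,31.93,33.93,Wallis Lake,NA,NA
Batemans Bay,MaxTemp,28.95,0.2,30.15,32.15,34.15,Wallis Lake,NA,NA
Wagonga Inlet,MaxTemp,28.75,0.2,29.95,31.95,33.95,Wallis Lake,NA,NA
Bermagui,MaxTemp,26.16,0.2,27.36,29.36,31.36,Brisbane Water,Wallis Lake,Botany Bay
Merimbula,MaxTemp,25.85,0.2,27.05,29.05,31.05,Brisbane Water,Wallis Lake,Botany Bay
Pambula,MaxTemp,26.13,0.2,27.33,29.33,31.33,Brisbane Water,Wallis Lake,Botany Bay
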