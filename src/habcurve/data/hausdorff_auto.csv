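habitat,segment,mean_hausdorff_m,max_hausdorff_m
r,769212,11.30,60.05
r,769214,9.30,29.58
r,769220,9.24,37.54
r,769229,14.41,34.13
r,769235,8.81,30.96
r,769244,17.45,77.86
r,769245,17.42,73.02
r,769259,14.86,56.34
m,769209,14.04,56.48
m,769213,18.68,56.54
m,769215,6.71,18.45
m,769216,8.05,35.54
m,769222,18.12,46.13
m,769234,19.14,85.89
m,769236,12.73,43.09
m,769266,9.35,32.43
n,769205,11.91,37.97
n,769206,12.87,33.76
n,769207,11.32,45.92
n,769208,15.36,50.45
n,769228,22.51,64.99
n,769233,22.08,64.69
n,769254,19.68,90.58
n,769258,25.75,116.82
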