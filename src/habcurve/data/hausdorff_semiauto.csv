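habitat,segment,mean_hausdorff_m,max_hausdorff_m
r,769212,7.20,22.77
r,769214,8.47,29.92
r,769220,4.91,17.67
r,769229,13.53,37.15
r,769235,11.33,36.67
r,769244,9.69,26.84
r,769245,6.98,20.46
r,769259,11.31,48.63
m,769209,6.92,17.48
m,769213,12.74,49.37
m,769215,5.04,24.01
m,769216,7.12,20.22
m,769222,8.56,26.32
m,769234,6.75,26.73
m,769236,7.32,19.41
m,769266,6.18,20.08
n,769205,11.27,31.74
n,769206,8.13,24.39
n,769207,10.39,35.15
n,769208,9.48,27.10
n,769228,12.06,42.18
n,769233,8.24,34.16
n,769254,8.09,22.02
n,769258,10.97,27.61
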