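# Reconstructed derived glycan trait panel for the IgA N-glycome.
# Built from the dominant-structure peak annotations shipped alongside;
# replace this file to use a laboratory's verbatim trait panel.
G0 = (GP1 + GP2 + GP3 + GP4) / (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP10 + GP11 + GP12 + GP13 + GP15 + GP16 + GP17 + GP18 + GP19 + GP20 + GP21 + GP22 + GP24 + GP26 + GP27 + GP28 + GP29 + GP30)
G1 = (GP6 + GP7 + GP8 + GP12 + GP15 + GP16) / (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP10 + GP11 + GP12 + GP13 + GP15 + GP16 + GP17 + GP18 + GP19 + GP20 + GP21 + GP22 + GP24 + GP26 + GP27 + GP28 + GP29 + GP30)
G2 = (GP10 + GP11 + GP13 + GP17 + GP18 + GP19 + GP20 + GP21 + GP22 + GP24) / (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP10 + GP11 + GP12 + GP13 + GP15 + GP16 + GP17 + GP18 + GP19 + GP20 + GP21 + GP22 + GP24 + GP26 + GP27 + GP28 + GP29 + GP30)
G3 = (GP26 + GP27 + GP28 + GP29 + GP30) / (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP10 + GP11 + GP12 + GP13 + GP15 + GP16 + GP17 + GP18 + GP19 + GP20 + GP21 + GP22 + GP24 + GP26 + GP27 + GP28 + GP29 + GP30)
S0 = (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP10 + GP11 + GP13) / (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP10 + GP11 + GP12 + GP13 + GP15 + GP16 + GP17 + GP18 + GP19 + GP20 + GP21 + GP22 + GP24 + GP26 + GP27 + GP28 + GP29 + GP30)
S1 = (GP12 + GP15 + GP16 + GP18 + GP20 + GP26) / (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP10 + GP11 + GP12 + GP13 + GP15 + GP16 + GP17 + GP18 + GP19 + GP20 + GP21 + GP22 + GP24 + GP26 + GP27 + GP28 + GP29 + GP30)
S2 = (GP17 + GP19 + GP21 + GP22 + GP24 + GP27 + GP28) / (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP10 + GP11 + GP12 + GP13 + GP15 + GP16 + GP17 + GP18 + GP19 + GP20 + GP21 + GP22 + GP24 + GP26 + GP27 + GP28 + GP29 + GP30)
S3 = (GP29 + GP30) / (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP10 + GP11 + GP12 + GP13 + GP15 + GP16 + GP17 + GP18 + GP19 + GP20 + GP21 + GP22 + GP24 + GP26 + GP27 + GP28 + GP29 + GP30)
B = (GP3 + GP4 + GP8 + GP12 + GP13 + GP20 + GP22 + GP24) / (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP10 + GP11 + GP12 + GP13 + GP15 + GP16 + GP17 + GP18 + GP19 + GP20 + GP21 + GP22 + GP24 + GP26 + GP27 + GP28 + GP29 + GP30)
CF = (GP1 + GP4 + GP6 + GP8 + GP10 + GP13 + GP16 + GP18 + GP20 + GP21 + GP22 + GP28 + GP30) / (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP10 + GP11 + GP12 + GP13 + GP15 + GP16 + GP17 + GP18 + GP19 + GP20 + GP21 + GP22 + GP24 + GP26 + GP27 + GP28 + GP29 + GP30)
HM = (GP5 + GP9 + GP14 + GP23 + GP25) / TOTAL
A3 = (GP26 + GP27 + GP28 + GP29 + GP30) / (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP10 + GP11 + GP12 + GP13 + GP15 + GP16 + GP17 + GP18 + GP19 + GP20 + GP21 + GP22 + GP24 + GP26 + GP27 + GP28 + GP29 + GP30)
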