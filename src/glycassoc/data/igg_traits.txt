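# Reconstructed derived glycan trait panel for the IgG N-glycome.
# Built from the dominant-structure peak annotations shipped alongside;
# replace this file to use a laboratory's verbatim trait panel.
G0 = (GP1 + GP2 + GP3 + GP4 + GP6) / (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP9 + GP10 + GP11 + GP12 + GP13 + GP14 + GP15 + GP17 + GP18 + GP19 + GP20 + GP21 + GP22 + GP23 + GP24)
G1 = (GP7 + GP8 + GP9 + GP10 + GP11 + GP17) / (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP9 + GP10 + GP11 + GP12 + GP13 + GP14 + GP15 + GP17 + GP18 + GP19 + GP20 + GP21 + GP22 + GP23 + GP24)
G2 = (GP12 + GP13 + GP14 + GP15 + GP18 + GP19 + GP20 + GP21 + GP22 + GP23 + GP24) / (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP9 + GP10 + GP11 + GP12 + GP13 + GP14 + GP15 + GP17 + GP18 + GP19 + GP20 + GP21 + GP22 + GP23 + GP24)
S0 = (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP9 + GP10 + GP11 + GP12 + GP13 + GP14 + GP15) / (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP9 + GP10 + GP11 + GP12 + GP13 + GP14 + GP15 + GP17 + GP18 + GP19 + GP20 + GP21 + GP22 + GP23 + GP24)
S1 = (GP17 + GP18 + GP19 + GP20) / (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP9 + GP10 + GP11 + GP12 + GP13 + GP14 + GP15 + GP17 + GP18 + GP19 + GP20 + GP21 + GP22 + GP23 + GP24)
S2 = (GP21 + GP22 + GP23 + GP24) / (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP9 + GP10 + GP11 + GP12 + GP13 + GP14 + GP15 + GP17 + GP18 + GP19 + GP20 + GP21 + GP22 + GP23 + GP24)
B = (GP3 + GP6 + GP10 + GP11 + GP13 + GP15 + GP20 + GP23 + GP24) / (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP9 + GP10 + GP11 + GP12 + GP13 + GP14 + GP15 + GP17 + GP18 + GP19 + GP20 + GP21 + GP22 + GP23 + GP24)
CF = (GP1 + GP4 + GP6 + GP8 + GP9 + GP10 + GP11 + GP14 + GP15 + GP17 + GP19 + GP20 + GP22 + GP23) / (GP1 + GP2 + GP3 + GP4 + GP6 + GP7 + GP8 + GP9 + GP10 + GP11 + GP12 + GP13 + GP14 + GP15 + GP17 + GP18 + GP19 + GP20 + GP21 + GP22 + GP23 + GP24)
HM = (GP5 + GP16) / TOTAL
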