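# Reconstructed derived glycan trait panel for the total plasma protein N-glycome.
# Built from the dominant-structure peak annotations shipped alongside;
# replace this file to use a laboratory's verbatim trait panel.
G0 = (GP1 + GP2 + GP3 + GP4) / (GP1 + GP2 + GP3 + GP4 + GP5 + GP6 + GP8 + GP9 + GP10 + GP11 + GP13 + GP14 + GP15 + GP16 + GP18 + GP20 + GP21 + GP22 + GP23 + GP24 + GP25 + GP26 + GP27 + GP28 + GP29 + GP30 + GP31 + GP32 + GP33 + GP34 + GP35 + GP36 + GP37 + GP38 + GP39)
G1 = (GP5 + GP6 + GP8 + GP13 + GP14) / (GP1 + GP2 + GP3 + GP4 + GP5 + GP6 + GP8 + GP9 + GP10 + GP11 + GP13 + GP14 + GP15 + GP16 + GP18 + GP20 + GP21 + GP22 + GP23 + GP24 + GP25 + GP26 + GP27 + GP28 + GP29 + GP30 + GP31 + GP32 + GP33 + GP34 + GP35 + GP36 + GP37 + GP38 + GP39)
G2 = (GP9 + GP10 + GP11 + GP15 + GP16 + GP18 + GP20 + GP21 + GP22 + GP23) / (GP1 + GP2 + GP3 + GP4 + GP5 + GP6 + GP8 + GP9 + GP10 + GP11 + GP13 + GP14 + GP15 + GP16 + GP18 + GP20 + GP21 + GP22 + GP23 + GP24 + GP25 + GP26 + GP27 + GP28 + GP29 + GP30 + GP31 + GP32 + GP33 + GP34 + GP35 + GP36 + GP37 + GP38 + GP39)
G3 = (GP24 + GP25 + GP26 + GP27 + GP28 + GP29 + GP30 + GP31 + GP32 + GP33 + GP34) / (GP1 + GP2 + GP3 + GP4 + GP5 + GP6 + GP8 + GP9 + GP10 + GP11 + GP13 + GP14 + GP15 + GP16 + GP18 + GP20 + GP21 + GP22 + GP23 + GP24 + GP25 + GP26 + GP27 + GP28 + GP29 + GP30 + GP31 + GP32 + GP33 + GP34 + GP35 + GP36 + GP37 + GP38 + GP39)
G4 = (GP35 + GP36 + GP37 + GP38 + GP39) / (GP1 + GP2 + GP3 + GP4 + GP5 + GP6 + GP8 + GP9 + GP10 + GP11 + GP13 + GP14 + GP15 + GP16 + GP18 + GP20 + GP21 + GP22 + GP23 + GP24 + GP25 + GP26 + GP27 + GP28 + GP29 + GP30 + GP31 + GP32 + GP33 + GP34 + GP35 + GP36 + GP37 + GP38 + GP39)
S0 = (GP1 + GP2 + GP3 + GP4 + GP5 + GP6 + GP8 + GP9 + GP10 + GP11) / (GP1 + GP2 + GP3 + GP4 + GP5 + GP6 + GP8 + GP9 + GP10 + GP11 + GP13 + GP14 + GP15 + GP16 + GP18 + GP20 + GP21 + GP22 + GP23 + GP24 + GP25 + GP26 + GP27 + GP28 + GP29 + GP30 + GP31 + GP32 + GP33 + GP34 + GP35 + GP36 + GP37 + GP38 + GP39)
S1 = (GP13 + GP14 + GP15 + GP16 + GP24) / (GP1 + GP2 + GP3 + GP4 + GP5 + GP6 + GP8 + GP9 + GP10 + GP11 + GP13 + GP14 + GP15 + GP16 + GP18 + GP20 + GP21 + GP22 + GP23 + GP24 + GP25 + GP26 + GP27 + GP28 + GP29 + GP30 + GP31 + GP32 + GP33 + GP34 + GP35 + GP36 + GP37 + GP38 + GP39)
S2 = (GP18 + GP20 + GP21 + GP22 + GP23 + GP25 + GP26 + GP27 + GP28 + GP30) / (GP1 + GP2 + GP3 + GP4 + GP5 + GP6 + GP8 + GP9 + GP10 + GP11 + GP13 + GP14 + GP15 + GP16 + GP18 + GP20 + GP21 + GP22 + GP23 + GP24 + GP25 + GP26 + GP27 + GP28 + GP29 + GP30 + GP31 + GP32 + GP33 + GP34 + GP35 + GP36 + GP37 + GP38 + GP39)
S3 = (GP29 + GP31 + GP32 + GP33 + GP34 + GP35 + GP36) / (GP1 + GP2 + GP3 + GP4 + GP5 + GP6 + GP8 + GP9 + GP10 + GP11 + GP13 + GP14 + GP15 + GP16 + GP18 + GP20 + GP21 + GP22 + GP23 + GP24 + GP25 + GP26 + GP27 + GP28 + GP29 + GP30 + GP31 + GP32 + GP33 + GP34 + GP35 + GP36 + GP37 + GP38 + GP39)
S4 = (GP37 + GP38 + GP39) / (GP1 + GP2 + GP3 + GP4 + GP5 + GP6 + GP8 + GP9 + GP10 + GP11 + GP13 + GP14 + GP15 + GP16 + GP18 + GP20 + GP21 + GP22 + GP23 + GP24 + GP25 + GP26 + GP27 + GP28 + GP29 + GP30 + GP31 + GP32 + GP33 + GP34 + GP35 + GP36 + GP37 + GP38 + GP39)
B = (GP2 + GP4 + GP6 + GP11 + GP22 + GP23) / (GP1 + GP2 + GP3 + GP4 + GP5 + GP6 + GP8 + GP9 + GP10 + GP11 + GP13 + GP14 + GP15 + GP16 + GP18 + GP20 + GP21 + GP22 + GP23 + GP24 + GP25 + GP26 + GP27 + GP28 + GP29 + GP30 + GP31 + GP32 + GP33 + GP34 + GP35 + GP36 + GP37 + GP38 + GP39)
CF = (GP1 + GP2 + GP5 + GP6 + GP9 + GP11 + GP13 + GP16 + GP21 + GP22 + GP26 + GP28 + GP30 + GP31 + GP33 + GP34 + GP36 + GP38) / (GP1 + GP2 + GP3 + GP4 + GP5 + GP6 + GP8 + GP9 + GP10 + GP11 + GP13 + GP14 + GP15 + GP16 + GP18 + GP20 + GP21 + GP22 + GP23 + GP24 + GP25 + GP26 + GP27 + GP28 + GP29 + GP30 + GP31 + GP32 + GP33 + GP34 + GP35 + GP36 + GP37 + GP38 + GP39)
LB = (GP1 + GP2 + GP3 + GP4 + GP5 + GP6 + GP8 + GP9 + GP10 + GP11 + GP13 + GP14 + GP15 + GP16 + GP18 + GP20 + GP21 + GP22 + GP23) / (GP1 + GP2 + GP3 + GP4 + GP5 + GP6 + GP8 + GP9 + GP10 + GP11 + GP13 + GP14 + GP15 + GP16 + GP18 + GP20 + GP21 + GP22 + GP23 + GP24 + GP25 + GP26 + GP27 + GP28 + GP29 + GP30 + GP31 + GP32 + GP33 + GP34 + GP35 + GP36 + GP37 + GP38 + GP39)
HB = (GP24 + GP25 + GP26 + GP27 + GP28 + GP29 + GP30 + GP31 + GP32 + GP33 + GP34 + GP35 + GP36 + GP37 + GP38 + GP39) / (GP1 + GP2 + GP3 + GP4 + GP5 + GP6 + GP8 + GP9 + GP10 + GP11 + GP13 + GP14 + GP15 + GP16 + GP18 + GP20 + GP21 + GP22 + GP23 + GP24 + GP25 + GP26 + GP27 + GP28 + GP29 + GP30 + GP31 + GP32 + GP33 + GP34 + GP35 + GP36 + GP37 + GP38 + GP39)
HM = (GP7 + GP12 + GP17 + GP19) / TOTAL
A2 = (GP1 + GP2 + GP3 + GP4 + GP5 + GP6 + GP8 + GP9 + GP10 + GP11 + GP13 + GP14 + GP15 + GP16 + GP18 + GP20 + GP21 + GP22 + GP23) / TOTAL
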