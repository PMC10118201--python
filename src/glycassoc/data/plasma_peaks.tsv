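peak_id	structure
GP1	FA2
GP2	FA2B/M5
GP3	A2
GP4	A2B
GP5	FA2G1
GP6	FA2[6]BG1
GP7	M6/FA2[3]BG1
GP8	A2G1
GP9	FA2G2
GP10	A2G2
GP11	FA2BG2
GP12	M7
GP13	FA2G1S1
GP14	A2G1S1
GP15	A2G2S1
GP16	FA2G2S1
GP17	M8
GP18	A2G2S2
GP19	M9
GP20	A2G2S2
GP21	FA2G2S2
GP22	FA2BG2S2
GP23	A2BG2S2
GP24	A3G3S1
GP25	A3G3S2
GP26	FA3G3S2
GP27	A3G3S2
GP28	FA3G3S2
GP29	A3G3S3
GP30	FA3G3S2
GP31	FA3G3S3/A3G3S3
GP32	A3G3S3
GP33	FA3G3S3
GP34	FA3G3S3/A4G4S3
GP35	A4G4S3
GP36	FA4G4S3
GP37	A4G4S4
GP38	FA4G4S4
GP39	A4G4S4
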