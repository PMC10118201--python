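peak_id	structure
GP1	FA2
GP2	A2
GP3	A2B
GP4	FA2B
GP5	M5
GP6	FA2G1
GP7	A2G1
GP8	FA2BG1
GP9	M6
GP10	FA2G2
GP11	A2G2
GP12	A2BG1S1
GP13	FA2BG2
GP14	M7
GP15	A2G1S1
GP16	FA2G1S1
GP17	A2G2S2
GP18	FA2G2S1
GP19	A2G2S2
GP20	FA2BG2S1
GP21	FA2G2S2
GP22	FA2BG2S2
GP23	M8
GP24	A2BG2S2
GP25	M9
GP26	A3G3S1
GP27	A3G3S2
GP28	FA3G3S2
GP29	A3G3S3
GP30	FA3G3S3
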