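peak_id	structure
GP1	FA1
GP2	A2
GP3	A2B
GP4	FA2
GP5	M5
GP6	FA2B/A2[6]G1
GP7	A2[3]G1
GP8	FA2[6]G1
GP9	FA2[3]G1
GP10	FA2[6]BG1
GP11	FA2[3]BG1
GP12	A2G2
GP13	A2BG2
GP14	FA2G2
GP15	FA2BG2
GP16	M6
GP17	FA2G1S1
GP18	A2G2S1
GP19	FA2G2S1
GP20	FA2BG2S1
GP21	A2G2S2
GP22	FA2G2S2
GP23	FA2BG2S2
GP24	A2BG2S2
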