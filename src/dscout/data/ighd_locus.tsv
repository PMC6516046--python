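name	imgt_name	position	length
D1	IGHD1-1	105919502	17
D2	IGHD2-2	105916826	31
D3	IGHD3-3	105914359	31
D4	IGHD4-4	105913222	16
D5	IGHD5-5	105912257	20
D6	IGHD6-6	105910410	18
D7	IGHD1-7	105909907	17
D8	IGHD2-8	105907211	31
D9	IGHD3-9	105904681	31
D10	IGHD3-10	105904497	31
D4	IGHD4-11	105903616	16
D12	IGHD5-12	105902649	23
D13	IGHD6-13	105901142	21
D14	IGHD1-14	105900638	17
D15	IGHD2-15	105897957	31
D16	IGHD3-16	105895634	37
D17	IGHD4-17	105894508	16
D5	IGHD5-18	105893542	20
D19	IGHD6-19	105891699	21
D20	IGHD1-20	105891191	17
D21	IGHD2-21	105888551	28
D22	IGHD3-22	105886031	31
D23	IGHD4-23	105884870	19
D24	IGHD5-24	105883903	20
D25	IGHD6-25	105881539	18
D26	IGHD1-26	105881034	20
D27	IGHD7-27	105865551	11
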