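chromosome	length_bp	centromere_bp
1	247249719	121300000
2	242951149	93300000
3	199501827	91700000
4	191273063	50700000
5	180857866	47700000
6	170899992	60500000
7	158821424	59100000
8	146274826	45200000
9	140273252	51800000
10	135374737	40300000
11	134452384	52900000
12	132349534	35400000
13	114142980	17900000
14	106368585	17600000
15	100338915	19000000
16	88827254	36600000
17	78774742	24000000
18	76117153	17200000
19	63811651	26500000
20	62435964	28100000
21	46944323	13200000
22	49691432	14700000
X	154913754	60600000
Y	57772954	12500000
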