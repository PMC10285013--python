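station,tow,latitude,longitude,volume_m3,total_mp,mp_per_m3_printed,clogged
18-1,1,31 39.920 N,024 27.287 W,270,41,0.152,False
18-1,2,31 40.476 N,024 28.369 W,196,283,1.444,False
18-1,3,31 41.038 N,024 29.374 W,228,38,0.167,False
43-1,1,31 19.496 N,029 34.347 W,174,152,0.874,False
43-1,2,31 20.462 N,029 35.133 W,24,82,3.417,True
43-1,3,31 21.472 N,029 35.958 W,98,63,0.643,False
48-1,1,31 19.939 N,030 41.100 W,333,53,0.159,False
48-1,2,31 20.671 N,030 42.267 W,325,98,0.302,False
48-1,3,31 21.545 N,030 43.284 W,292,108,0.370,False
55-1,1,31 07.098 N,033 49.016 W,204,214,1.049,False
55-1,2,31 07.953 N,033 49.748 W,176,280,1.591,False
55-1,3,31 09.021 N,033 50.493 W,81,293,3.617,False
68-1,1,32 10.424 N,034 09.152 W,176,28,0.159,False
68-1,2,32 11.403 N,034 09.900 W,244,54,0.221,False
68-1,3,32 12.425 N,034 10.645 W,144,81,0.563,True
78-1,1,33 08.520 N,034 33.673 W,204,75,0.368,False
78-1,2,33 09.608 N,034 34.564 W,269,28,0.104,False
78-1,3,33 10.708 N,034 35.527 W,27,194,7.185,True
87-1,1,33 20.447 N,033 49.999 W,212,41,0.193,False
87-1,2,33 21.646 N,033 49.509 W,206,13,0.063,False
87-1,3,33 22.754 N,033 49.090 W,257,24,0.093,False
107-1,1,35 08.367 N,020 49.280 W,297,24,0.081,False
107-1,2,35 09.270 N,020 48.266 W,333,34,0.102,False
107-1,3,35 10.310 N,020 47.104 W,291,40,0.137,False
107-1,4,35 11.257 N,020 46.044 W,285,35,0.123,False
107-1,5,35 12.198 N,020 44.991 W,308,24,0.078,False
107-1,6,35 13.206 N,020 43.862 W,272,18,0.066,False
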