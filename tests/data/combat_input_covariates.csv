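batch,age,sex
A,29.0934409,1
A,32.67033359,0
A,51.89461829,1
A,47.05018683,1
A,35.64438202,1
A,33.31255711,0
A,43.93235014,1
A,27.46936742,1
A,46.91024176,0
A,57.67211461,0
A,29.92982859,0
A,57.95524607,0
A,46.68949812,1
A,23.83591742,0
A,37.67358665,1
A,55.45919677,0
A,47.89814,0
A,33.05891456,0
A,49.35712653,0
A,28.80539822,1
B,23.26378278,0
B,26.39582404,0
B,33.6040074,1
B,38.60772615,0
B,30.65684113,1
B,52.63105614,1
B,27.73177557,0
B,25.17876305,0
B,23.66659006,0
B,43.94272055,0
B,54.18967617,1
B,44.06484967,0
B,57.27953445,1
B,48.99125444,0
B,54.4220527,1
B,57.17351206,0
B,41.84744036,1
B,57.50691835,0
B,39.7995176,0
B,30.9509273,0
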