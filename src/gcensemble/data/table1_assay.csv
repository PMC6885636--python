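variant,measure,mean,sem,n
WT,luciferase,274,86,3
aV587I/aV589T,luciferase,1220,229,3
aV587I/aV589T/aK590R,luciferase,667,165,3
aM591N,luciferase,1264,206,3
bI533M,luciferase,1298,245,3
bM537N,luciferase,738,132,3
bP538Q,luciferase,1244,331,3
aV587I/aV589T/aK590R/bM537N,luciferase,1062,72,3
ab-flap-deletions,luciferase,1688,101,3
aM591N/bM537N,luciferase,2623,496,3
aC595S,luciferase,579,135,3
aC595S/bT474V,luciferase,2668,463,3
bT474V,luciferase,1250,311,3
bT474M,luciferase,1726,381,3
aC595S/aE526A,luciferase,3366,1315,3
aC595Y,luciferase,677,5,3
aC595S/bM537N,luciferase,965,246,3
aC595S/bM537N/bP538Q,luciferase,1925,241,3
aC595S/bP538Q,luciferase,439,124,3
bC541G,luciferase,1802,374,3
bC541G/aC595S,luciferase,2060,190,3
bC541G/aC595S/bM537N,luciferase,1958,344,3
bC541G/aC595S/bM537N/bP538Q,luciferase,297,70,3
WT,cgmp,1.9,0.5,3
aV587I/aV589T,cgmp,3.8,0.9,3
aV587I/aV589T/aK590R,cgmp,3.7,1.1,3
aM591N,cgmp,3.7,0.5,3
bI533M,cgmp,2.9,1.4,3
bM537N,cgmp,4.2,0.9,3
bP538Q,cgmp,2.7,0.8,3
aV587I/aV589T/aK590R/bM537N,cgmp,3.5,2.0,3
ab-flap-deletions,cgmp,3.2,0.8,3
aM591N/bM537N,cgmp,4.5,1.2,3
aC595S,cgmp,12.2,2.0,3
aC595S/bT474V,cgmp,6.4,1.3,3
bT474V,cgmp,3.9,1.4,3
bT474M,cgmp,4.4,0.5,3
aC595S/aE526A,cgmp,9.4,1.5,3
aC595Y,cgmp,0.5,0.3,3
aC595S/bM537N,cgmp,19.5,4.1,3
aC595S/bM537N/bP538Q,cgmp,9.2,2.3,3
aC595S/bP538Q,cgmp,2.0,0.8,3
bC541G,cgmp,4.1,1.2,3
bC541G/aC595S,cgmp,24.8,1.4,3
aC595S/bM537N/bN548W,cgmp,1.5,0.3,3
bC541G/aC595S/bM537N,cgmp,28.6,4.6,3
bC541G/aC595S/bM537N/bP538Q,cgmp,10.0,1.7,3
WT,camp,0.6,0.1,3
aC595Y,camp,1.3,0.4,3
bC541G,camp,4.5,1.3,3
bC541G/aC595S,camp,3.7,1.5,3
bC541G/aC595S/bM537N,camp,3.1,0.8,3
bC541G/aC595S/bM537N/bP538Q,camp,1.8,0.4,3
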