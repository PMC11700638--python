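category,label,count_before,count_after
1a,"Sadness, grief, depression, melancholy",56,47
1b,"Distress (sadness and worry)",21,16
1c,"Suffering",16,14
2,"Anger",62,53
3a,"Happiness, joy",44,35
3b,"Schadenfreude",3,2
3c,"Pleasure (as part of Joy)",2,2
4,"Fear, anxiety, panic, nervousness, awe, respect",47,37
5,"Despise, hate, contempt",18,17
6a,"Love, affection, admiration",13,9
6b,"Desire (as a part of love)",6,6
7,"Disgust",6,5
8,"Sympathy, compassion, pity",10,7
9,"Envy, jealousy",1,1
10,"Pride",16,15
11,"Surprise",2,2
12,"Shame, embarrassment",2,1
13,"Sexual arousal",6,6
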