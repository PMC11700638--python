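word,primary_category,1a,1b,1c,2,3a,3b,3c,4,5,6a,6b,7,8,9,10,11,12,13,notes
ezēzu[be(come)-angry]V,2,No,No,No,Yes,No,No,No,No,No,No,No,No,No,No,No,No,No,No,direct emotional meaning
ulṣu[pleasure]N,3c,No,No,No,No,No,No,Yes,No,No,No,No,No,No,No,No,No,No,Yes,joy with a nuance of sexual pleasure
ḫadû[be(come)-joyful]V,3a,No,No,No,No,Yes,No,No,No,No,No,No,No,No,No,No,No,No,No,
adāru[be(come)-dark]V,4,No,No,No,No,No,No,No,Yes,No,No,No,No,No,No,No,No,No,No,idiomatic expression of fear
nissatu[grief]N,1a,Yes,Yes,No,No,No,No,No,No,No,No,No,No,No,No,No,No,No,No,grief or worry depending on context
râmu[love]V,6a,No,No,No,No,No,No,No,No,No,Yes,No,No,No,No,No,No,No,No,
šuḫarruru[be-deathly-still]V,11,No,No,No,No,No,No,No,Yes,No,No,No,No,No,No,No,Yes,No,No,negative surprise and shock
bâšu[shame]V,12,No,No,No,No,No,No,No,No,No,No,No,No,No,No,No,No,Yes,No,
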