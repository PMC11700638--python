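word,gloss,atlas_parts,excluded,reason
kabattu[liver]N,liver,liver,no,none
nupāru[heart]N,heart,heart,no,none
karšu[stomach]N,stomach,stomach,no,none
kalītu[kidney]N,kidney,kidney,no,none
qaqqadu[head]N,head,head,no,none
gulgullu[skull]N,skull,skull,no,none
eṣemṣēru[backbone]N,backbone,backbone,no,none
idu[arm]N,arm,arm,no,none
qātu[hand]N,hand,hand,no,none
purīdu[leg]N,leg,leg,no,none
šēpu[foot]N,foot,foot,no,none
mašku[skin]N,skin,skin,no,none
ušultu[vein]N,vein,,yes,whole-body-system
libbu[interior]N,interior,,yes,ambiguous-general-term
rēmu[womb]N,womb,,yes,female-anatomy-unsupported
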