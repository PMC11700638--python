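word_name,part_name
backbone,spine
vertebra,spine
belly,stomach
temple,skull
cheek,skull
face,head
nose,head
lip,head
throat,head
neck,head
rump,leg
back,spine
shoulder,arm
armpit,arm
knee,leg
shin,leg
thigh,leg
ankle,foot
breast,heart
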