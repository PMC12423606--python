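system_id	ig	title
ncd-gamedata	1	NCD Gamedata
ncd-lifestyle	1	NCD Lifestyle data
ncd-bct	0	NCD Behavior Change Techniques
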