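level	element
1	title
1	publisher
1	language
1	platform
1	characterizing-goal
1	target-group
2	genre
2	bct-list
2	play-duration
3	application-profile
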