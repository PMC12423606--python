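req_id	description	level	req_type	key_area
R01	Integration of behavior change techniques as core game mechanics	must	functional	C2
R02	Integration of engaging gamification elements for applications	must	functional	C2
R03	Learning and educational aspects	should	functional	C2
R04	Emphasizing good interaction design and usability	should	nonfunctional	C5
R05	Use of appealing game graphics	may	nonfunctional	C5
R06	Integration of music and sound effects	may	nonfunctional	C5
R07	Considering suitable game genres	may	nonfunctional	C2
R08	Applying intuitive controls	must	nonfunctional	C5
R09	Integration of social support and interaction	may	functional	C2
R10	Availability of games and applications	must	nonfunctional	C4
R11	Games and applications should come at a low cost for users	should	nonfunctional	C4
R12	Suitable (hardware) platform for low entry barrier	should	nonfunctional	C4
R13	Inclusion of therapists and clinicians	must	nonfunctional	C1
R14	Ability to extract data in a semantically interoperable way	must	functional	C3
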