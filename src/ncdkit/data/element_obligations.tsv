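path	obligation	risk_factor	category	code_system	code
composition.export-period	M
composition.export-date	M
composition.din-metadata	M
composition.subject	M
composition.practitioner	O
composition.related-persons	O
section.clinical	M
section.game	M
section.lifestyle	M
entry.clinical.blood-glucose	D	hyperglycemia	clinical	loinc	2339-0
entry.clinical.carbohydrate-intake	D	hyperglycemia	clinical	loinc	9059-7
entry.clinical.insulin-dosage	D	hyperglycemia	clinical	loinc	96596-5
entry.clinical.physical-activity	O		clinical	loinc	55411-3
entry.clinical.nutrition-intake	D	nutrition	clinical	loinc	81939-1
entry.clinical.stress-score	O		clinical	loinc	93038-8
entry.lifestyle.mood	D	mental-health	lifestyle	ncd-lifestyle	mood
entry.lifestyle.tobacco-use	D	smoking	lifestyle	ncd-lifestyle	tobacco-use
entry.lifestyle.alcohol-consumption	O		lifestyle	ncd-lifestyle	alcohol-consumption
entry.lifestyle.diary-entry	O		lifestyle	ncd-lifestyle	diary-entry
entry.game.achievement	O		game	ncd-gamedata	achievement
entry.game.high-score	O		game	ncd-gamedata	high-score
entry.game.other	O		game	ncd-gamedata	other
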