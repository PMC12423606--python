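archetype_id	name	app_type	platform	main_risk_factor	produced_elements	best_effort
G1	BreathIn	serious game	Android	smoking	entry.lifestyle.tobacco-use;entry.lifestyle.diary-entry;entry.game.achievement	0
G2	Food Pyramid Escape	serious game	Android	nutrition	entry.clinical.nutrition-intake;entry.game.high-score;entry.game.other	1
G3	Nutrition Garden	gamified app	Android	nutrition	entry.clinical.nutrition-intake;entry.lifestyle.diary-entry;entry.game.achievement	1
G4	NutritionRush	serious game	Android	nutrition	entry.clinical.nutrition-intake;entry.game.high-score	1
G5	NutriMine	modification	PC	nutrition	entry.clinical.nutrition-intake;entry.game.other	1
G6	recoverApp	gamified app	Android and PC	mental-health	entry.lifestyle.mood;entry.lifestyle.diary-entry;entry.game.achievement	0
G7	MoodBooster	gamified app	Android	mental-health	entry.lifestyle.mood;entry.clinical.stress-score;entry.lifestyle.diary-entry;entry.game.achievement	0
G8	DiaBeaThis	gamified web application	Web (PC and mobile)	hyperglycemia	entry.clinical.blood-glucose;entry.clinical.carbohydrate-intake;entry.clinical.insulin-dosage;entry.clinical.physical-activity;entry.lifestyle.mood;entry.lifestyle.diary-entry;entry.game.other	0
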