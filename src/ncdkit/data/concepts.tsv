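system_id	code	display	definition
ncd-gamedata	achievement	Achievement	An in-game achievement, badge, or comparable unlocked reward.
ncd-gamedata	high-score	High score	A best score attained in a game or minigame.
ncd-gamedata	other	Other game data	Any other game datum; entries using this code must qualify it in free text.
ncd-lifestyle	mood	Mood	A self-reported mood or state-of-mind rating.
ncd-lifestyle	alcohol-consumption	Alcohol consumption	A self-reported quantity of alcohol consumed.
ncd-lifestyle	tobacco-use	Tobacco use	A self-reported quantity of tobacco consumed, e.g. cigarettes smoked.
ncd-lifestyle	diary-entry	Diary entry	A free-text diary note recorded by the user.
ncd-bct	information-about-health-consequences	Information about health consequences	Provide information about health consequences of performing the behavior.
ncd-bct	self-monitoring-of-behavior	Self-monitoring of behavior	Establish a method for the person to monitor and record their behavior.
ncd-bct	feedback-on-behavior	Feedback on behavior	Monitor and provide informative or evaluative feedback on the behavior.
ncd-bct	incentive-outcome	Incentive (outcome)	Inform that a reward will be delivered if there has been effort or progress, e.g. achievements, badges, points.
ncd-bct	social-support	Social support	Arrange or provide social support for performance of the behavior, e.g. a chat feature.
ncd-bct	graded-tasks	Graded tasks	Set easy-to-perform tasks, making them increasingly difficult until the behavior is performed.
ncd-bct	social-comparison	Social comparison	Draw attention to others' performance to allow comparison, e.g. a leaderboard or versus game.
ncd-bct	goal-setting	Goal setting	Set or agree on a goal defined in terms of the behavior to be achieved.
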