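# Default pattern rules: name<TAB>field_code<TAB>priority<TAB>pattern
# pattern = space-separated per-token regexes, matched case-insensitively
# against normalized tokens (trailing clause punctuation stripped).
du_until_symptom	du	95	until	the	\w+	(disappears|resolves|subsides)
du_as_long_as_needed	du	94	as	long	as	needed
du_for_n_period	du	92	for	(\d+|one|two|three|four|five|six|seven|eight|nine|ten)	(days?|weeks?|months?)
du_for_a_period	du	92	for	a	(day|week|month|year)
du_x_days	du	91	x\d+	(days?|weeks?|months?)
du_day_course	du	91	\d+-day	course
du_during_break	du	90	during	(spring|summer|winter|fall)	break
f_q_n_prn	f	78	q	\d+(-\d+)?	prn
f_q_n_hours	f	77	q	\d+(-\d+)?	(h|hrs?|hours?)
f_x_before_meal	f	76	x\d+	(before|after)	meals?
f_n_times_a_day	f	75	(one|two|three|four|five|six)	times	(a|per)	day
f_once_a_day	f	74	(once|twice)	(a|per)	day
f_as_needed	f	72	as	needed
f_every_morning	f	72	every	(morning|evening|night|day)
f_prn	f	70	prn
f_abbrev	f	70	(qd|bid|tid|qid|qhs|qam|q\.d\.?|b\.i\.d\.?|t\.i\.d\.?|q\.i\.d\.?|q\.h\.s\.?)
f_daily	f	69	(daily|nightly|weekly)
mo_by_mouth	mo	66	(by|per)	(mouth|rectum|tube)
mo_po	mo	65	(po|p\.o\.?|iv|i\.v\.?|im|i\.m\.?|sc|s\.c\.?|sl|s\.l\.?)
mo_word	mo	65	(orally|oral|intravenous|intravenously|topical|topically|sublingual|subcutaneous|subcutaneously|intramuscular|intramuscularly|inhaled|nebulized|transdermal)
do_num_x_tablets	do	62	\d+(\.\d+)?	(mg|mcg|g|ml)	x	\d+	(tablets?|capsules?|tabs?)
do_num_unit	do	60	\d+(\.\d+)?(-\d+(\.\d+)?)?	(mg|mcg|g|ml|cc|meq|units?|tabs?|tablets?|capsules?|puffs?|drops?|sprays?|patch(es)?)
do_word_unit	do	60	(one|two|three|four|five|six|half)	(tablets?|capsules?|tabs?|puffs?|drops?|sprays?)
do_num_mg_alone	do	58	\d+(\.\d+)?(mg|mcg|ml)
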