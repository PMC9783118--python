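SOCIAL HISTORY	SOCIAL_HISTORY
SOCIAL HX	SOCIAL_HISTORY
HABITS	HABITS
ALLERGIES	ALLERGIES
ALLERGY	ALLERGIES
Follow up and Instructions	FOLLOW_UP_INSTRUCTIONS
FOLLOW UP AND INSTRUCTIONS	FOLLOW_UP_INSTRUCTIONS
FOLLOW-UP INSTRUCTIONS	FOLLOW_UP_INSTRUCTIONS
DISCHARGE INSTRUCTIONS	FOLLOW_UP_INSTRUCTIONS
HISTORY OF PRESENT ILLNESS	HISTORY_OF_PRESENT_ILLNESS
PAST MEDICAL HISTORY	PAST_MEDICAL_HISTORY
MEDICATIONS	MEDICATIONS
Alcohol	ALCOHOL
Tobacco	TOBACCO
Smoking	SMOKING
Drug history	DRUG_HISTORY
Drugs	DRUGS
EtOH	ETOH
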