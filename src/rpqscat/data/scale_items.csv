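scale,item_id,label,domain
rpq,headache,Headaches,somatic
rpq,dizziness,Feelings of dizziness,somatic
rpq,nausea,Nausea and/or vomiting,somatic
rpq,noise_sensitivity,Noise sensitivity,somatic
rpq,sleep_disturbance,Sleep disturbance,sleep
rpq,fatigue,"Fatigue, tiring more easily",unclassified
rpq,irritability,"Being irritable, easily angered",emotional
rpq,depression,Feeling depressed or tearful,emotional
rpq,frustration,Feeling frustrated or impatient,emotional
rpq,forgetfulness,"Forgetfulness, poor memory",cognitive
rpq,poor_concentration,Poor concentration,cognitive
rpq,slowed_thinking,Taking longer to think,cognitive
rpq,blurred_vision,Blurred vision,unclassified
rpq,light_sensitivity,Light sensitivity,somatic
rpq,double_vision,Double vision,unclassified
rpq,restlessness,Restlessness,unclassified
scat,headache,Headache,somatic
scat,head_pressure,Pressure in head,somatic
scat,neck_pain,Neck pain,somatic
scat,nausea,Nausea or vomiting,somatic
scat,dizziness,Dizziness,somatic
scat,blurred_vision,Blurred vision,unclassified
scat,balance_problems,Balance problems,somatic
scat,light_sensitivity,Sensitivity to light,somatic
scat,noise_sensitivity,Sensitivity to noise,somatic
scat,slowed_down,Feeling slowed down,unclassified
scat,foggy,Feeling like in a fog,cognitive
scat,not_right,Don't feel right,unclassified
scat,concentration_difficulty,Difficulty concentrating,cognitive
scat,memory_difficulty,Difficulty remembering,cognitive
scat,fatigue,Fatigue or low energy,somatic
scat,confusion,Confusion,cognitive
scat,drowsiness,Drowsiness,sleep
scat,trouble_falling_asleep,Trouble falling asleep,sleep
scat,more_emotional,More emotional,emotional
scat,irritability,Irritability,emotional
scat,sadness,Sadness,emotional
scat,nervous_anxious,Nervous or anxious,emotional
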