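subject,breed,recording_min,resting_min,acc_rest_ess,acc_rest_posture,acc_recumbent_alert_lmr,spc_recumbent_alert_lmr,npv_recumbent_alert_lmr
Grizzly,Rottweiler Mix,202.70,185.96,0.87,0.89,0.92,0.96,0.90
Santiago,Pit Bull Mix,136.49,133.85,0.95,0.87,0.91,0.92,0.97
Molly,Shih Tzu,91.57,90.96,0.90,0.89,0.94,0.98,0.95
Cannoli,Cavalier King Charles/Bichon Frise,95.60,80.68,0.83,0.87,0.84,0.95,0.90
Oscar,Pug,126.30,124.86,0.91,0.97,0.91,0.92,0.96
Layla,Labrador Mix,194.76,184.88,0.91,0.91,0.85,0.66,0.97
Rico,Labrador Mix,198.43,181.93,0.90,0.86,0.78,0.69,0.97
Bruno,Labrador/Poodle,121.05,61.85,0.81,0.78,0.74,0.91,0.95
Ginger,Bulldog Mix,89.80,85.41,0.86,0.97,0.97,0.48,0.98
Charlie,Cavalier King Charles,90.82,89.42,0.78,0.93,0.99,0.98,0.97
Penny,English Toy Spaniel,75.74,73.91,0.65,0.84,0.95,0.86,0.87
Lulu,Terrier Mix,125.25,123.05,0.93,0.94,0.95,0.84,0.95
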