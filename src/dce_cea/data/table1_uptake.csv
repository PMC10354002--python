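# Published uptake projections per intervention scenario: conditional-logit
# coefficient, percentage-point usage increase from a 30.60% baseline
# share, its SE and 95% CI, and the resulting total share of adolescents
# among all clinic users. The printed deltas are authoritative inputs for
# downstream projections (they are not regenerable from the rounded
# coefficients). Scenario keys join attribute names with '+'; the row
# keyed *_dup reproduces a duplicated printed label.
scenario,printed_name,coefficient,delta_pp,se,p_value,ci_low_pp,ci_high_pp,total_share_pct,modifiable
afternoon,Afternoon,0.01,0.82,0.03,0.80,-5.62,7.27,31.42,true
wifi,Wi-Fi,0.03,2.71,0.04,0.45,-4.25,9.67,33.31,true
youth_only,Youth waiting area,0.00,0.29,0.03,0.93,-6.17,6.74,30.89,true
food,Food,0.02,2.25,0.03,0.49,-4.10,8.61,32.85,true
friendly,Friendly,0.19,18.54,0.03,0.00,13.44,23.63,49.14,false
confidential,Confidential,0.08,8.35,0.03,0.00,3.09,13.60,38.95,false
food+wifi,Wi-Fi and food,0.11,10.70,0.05,0.03,10.00,20.00,41.30,true
food+youth_only,Food and youth,0.08,8.30,0.04,0.06,0.00,16.00,38.90,true
wifi+youth_only,Youth and Wi-Fi,0.09,9.00,0.04,0.07,0.00,18.00,39.60,true
afternoon+wifi,Afternoon and Wi-Fi,0.09,9.00,0.04,0.02,1.20,17.00,39.60,true
afternoon+youth_only,Afternoon and youth-only,0.07,6.90,0.04,0.08,-0.87,14.67,37.50,true
afternoon+food,Food and afternoon,0.08,8.00,0.03,0.02,1.20,16.40,38.60,true
afternoon+wifi+youth_only,"Youth-only, afternoon and Wi-Fi",0.17,16.84,0.06,0.01,4.59,29.08,47.44,true
food+wifi+youth_only,"Wi-Fi, food and youth",0.17,16.70,0.06,0.01,4.50,28.80,47.30,true
afternoon+food+wifi,"Wi-Fi, food and afternoon",0.17,17.20,0.05,0.00,6.90,27.48,47.80,true
afternoon+food+youth_only,"Food, afternoon and youth",0.15,14.80,0.05,0.00,5.48,24.24,45.40,true
afternoon+food+wifi+youth_only,"Wi-Fi, food, afternoon and youth",0.23,23.00,3.65,0.00,10.60,35.00,53.60,true
afternoon+friendly+wifi+youth_only,"Youth-only, Wi-Fi, afternoon and friendly",0.49,49.42,0.04,0.00,40.86,57.99,80.02,false
afternoon+friendly+wifi+youth_only_dup,"Youth-only, Wi-Fi, afternoon and friendly (duplicated printed label)",0.38,37.99,0.05,0.00,28.60,47.38,68.59,false
afternoon+confidential+food+friendly+wifi+youth_only,"Youth-only, Wi-Fi, food, afternoon, friendly and confidentiality",0.55,55.00,0.05,0.00,46.00,65.00,85.60,false
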