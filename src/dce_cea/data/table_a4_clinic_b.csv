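# Published Clinic B one-way sensitivity table (lower CI bound of uptake),
# shipped for reference only: the printed cost-per-additional column is
# visibly misaligned against the totals, so no numeric check pins these
# values. Currency columns in USD.
scenario,printed_name,additional_per_month,total_per_month,pct_change,cost_per_additional_usd,total_cost_usd,printed_status,printed_icer_usd
wifi,Wi-Fi,1,1809,-4.3,11.01,11.01,Dominated,
food,Food,1,1809,-4.1,31.82,31.82,Dominated,
afternoon,Afternoon,1,1809,-5.6,80.07,80.07,Dominated,
youth_only,Youth-only,1,1809,-6.2,630.40,630.40,Dominated,
afternoon+wifi,Wi-Fi and afternoon,22,1830,1.2,1166.11,856.85,Dominated,
wifi+youth_only,Wi-Fi and youth-only,1,1809,0.0,81.54,1166.11,Dominated,
afternoon+youth_only,Afternoon and youth-only,22,1830,1.2,10.17,1769.81,Dominated,
food+wifi,Wi-Fi and food,181,1989,10.0,1907.59,1840.26,On frontier,6.18
food+youth_only,Food and youth-only,1,1809,0.0,27.82,1907.59,Dominated,
food+wifi+youth_only,"Wi-Fi, food and youth-only",81,1889,4.5,28.34,2264.65,Dominated,
afternoon+wifi+youth_only,"Wi-Fi, afternoon and youth-only",83,1891,4.6,2478.44,2350.82,Dominated,
afternoon+food,Food and afternoon,1,1809,-0.9,34.94,2478.44,Dominated,
afternoon+food+youth_only,"Food, afternoon and youth-only",99,1907,5.5,32.21,3463.00,Dominated,
afternoon+food+wifi,"Wi-Fi, food and afternoon",125,1933,6.9,21.64,4019.66,Dominated,
afternoon+food+wifi+youth_only,"Wi-Fi, food, afternoon and youth-only",192,2000,10.6,571.64,4148.30,On frontier,212.73
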