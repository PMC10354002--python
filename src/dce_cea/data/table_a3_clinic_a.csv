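# Published Clinic A one-way sensitivity table (lower CI bound of uptake),
# shipped for reference only: several cells are internally inconsistent
# (percent columns disagree with the CI bounds; counts floored at 1), so
# no numeric check pins these values. Currency columns in USD.
scenario,printed_name,additional_per_month,total_per_month,pct_change,cost_per_additional_usd,total_cost_usd,printed_status,printed_icer_usd
wifi,Wi-Fi,1,1532,-4.3,535.81,535.81,Dominated,
youth_only,Youth-only,1,1532,-6.2,929.29,929.29,Dominated,
afternoon,Afternoon,1,1532,-5.6,1015.51,1015.51,Dominated,
food,Food,1,1532,-4.1,1117.98,1117.98,Dominated,
food+youth_only,Food and youth-only,1,1532,0.0,1198.75,1198.75,Dominated,
wifi+youth_only,Wi-Fi and youth-only,1,1532,0.0,1497.53,1497.53,Dominated,
afternoon+wifi,Wi-Fi and afternoon,18,1549,1.2,87.96,1615.62,Dominated,
food+wifi,Wi-Fi and food,153,1684,10.0,11.52,1763.88,On frontier,1.10
afternoon+youth_only,Afternoon and youth-only,18,1549,1.2,109.35,2008.40,Dominated,
food+wifi+youth_only,"Wi-Fi, food and youth-only",69,1599,4.5,30.88,2126.94,Dominated,
afternoon+food,Food and afternoon,1,1532,-0.9,3252.15,3252.15,Dominated,
afternoon+wifi+youth_only,"Wi-Fi, afternoon and youth-only",70,1601,4.6,50.73,3560.49,Dominated,
afternoon+food+youth_only,"Food, afternoon and youth-only",84,1614,5.5,50.88,4267.50,Dominated,
afternoon+food+wifi,"Wi-Fi, food and afternoon",106,1636,6.9,41.29,4361.22,Dominated,
afternoon+food+wifi+youth_only,"Wi-Fi, food, afternoon and youth-only",162,1693,10.6,42.95,6969.09,On frontier,566.79
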