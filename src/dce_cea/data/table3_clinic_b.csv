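# Published Clinic B cost-effectiveness table (2019 USD, monthly), printed
# row order preserved. Currency columns in USD.
scenario,printed_name,additional_per_month,total_per_month,pct_change,cost_per_additional_usd,total_cost_usd,printed_status,printed_icer_usd
wifi,Wi-Fi,49,1857,2.7,10.66,522.69,Weakly dominated,
youth_only,Youth-only,5,1813,0.3,116.50,611.08,Dominated,
wifi+youth_only,Wi-Fi and youth-only,163,1971,9.0,7.01,1141.87,On frontier,7.01
afternoon,Afternoon,15,1823,0.8,77.58,1150.59,Dominated,
food,Food,41,1849,2.3,30.83,1254.73,Dominated,
food+youth_only,Food and youth-only,145,1953,8.0,11.43,1653.56,Dominated,
afternoon+youth_only,Afternoon and youth-only,125,1933,6.9,13.79,1720.92,Dominated,
food+wifi,Wi-Fi and food,199,2007,10.7,8.97,1785.57,Weakly dominated,
afternoon+wifi,Wi-Fi and afternoon,168,1976,9.3,7.45,1253.69,Dominated,
afternoon+food,Food and afternoon,163,1971,9.0,14.83,2413.33,Dominated,
food+wifi+youth_only,"Wi-Fi, food and youth-only",307,2115,17.0,8.10,2490.46,On frontier,9.32
afternoon+wifi+youth_only,"Wi-Fi, afternoon and youth-only",271,2079,15.0,8.45,2293.28,Dominated,
afternoon+food+wifi,"Wi-Fi, food and afternoon",307,2115,17.0,12.73,3914.33,Dominated,
afternoon+food+youth_only,"Food, afternoon and youth-only",271,2079,15.0,11.15,3025.94,Dominated,
afternoon+food+wifi+youth_only,"Wi-Fi, food, afternoon and youth-only",416,2224,23.0,9.76,4059.62,On frontier,14.45
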