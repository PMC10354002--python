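# Published Clinic A cost-effectiveness table (2019 USD, monthly).
# cost_per_additional_usd and total_cost_usd are currency columns in USD.
# printed_status / printed_icer_usd reproduce the published labels; the
# engine's own dominance labels can differ (see docs/methods.md).
scenario,printed_name,additional_per_month,total_per_month,pct_change,cost_per_additional_usd,total_cost_usd,printed_status,printed_icer_usd
wifi,Wi-Fi,41,1572,2.7,12.56,516.65,Dominated,
youth_only,Youth-only,4,1535,0.3,202.91,811.63,Dominated,
afternoon,Afternoon,13,1544,0.8,78.47,1020.14,Dominated,
food,Food,34,1565,2.3,31.54,1072.28,Dominated,
wifi+youth_only,Wi-Fi and youth-only,138,1669,9.0,10.62,1465.56,On frontier,9.78
food+wifi,Wi-Fi and food,168,1699,10.7,10.15,1705.92,Weakly dominated,
food+youth_only,Food and youth-only,122,1653,8.3,15.23,1858.50,Dominated,
afternoon+wifi,Wi-Fi and afternoon,142,1673,9.3,18.33,2603.24,Weakly dominated,
food+wifi+youth_only,"Wi-Fi, food and youth-only",260,1791,17.0,10.54,2739.87,On frontier,10.45
afternoon+youth_only,Afternoon and youth-only,106,1637,6.9,27.03,2864.78,Dominated,
afternoon+wifi+youth_only,"Wi-Fi, afternoon and youth-only",230,1761,17.0,13.68,3147.26,Dominated,
afternoon+food,Food and afternoon,138,1669,9.0,24.94,3441.86,Dominated,
afternoon+food+youth_only,"Food, afternoon and youth-only",230,1761,15.0,18.09,4160.93,Dominated,
afternoon+food+wifi,"Wi-Fi, food and afternoon",260,1791,17.0,16.35,4251.24,Dominated,
afternoon+food+wifi+youth_only,"Wi-Fi, food, afternoon and youth-only",352,1883,23.0,19.20,6757.95,On frontier,43.67
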