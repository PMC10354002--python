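# Conditional-logit coefficients (log-odds units) for single attribute
# levels relative to the baseline service (clinic location, morning hours,
# unfriendly staff, no confidentiality, no incentives).
attribute,level,coefficient,std_error,modifiable
wifi,Wi-Fi,0.03,0.04,true
food,Food,0.02,0.03,true
afternoon,Afternoon,0.01,0.03,true
youth_only,Youth-only,0.00,0.03,true
friendly,Friendly,0.19,0.03,false
confidential,Confidential,0.08,0.03,false
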