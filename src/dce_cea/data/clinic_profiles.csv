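# Clinic volumes: baseline adolescent clients per month (published totals
# minus additional in any single-attribute row), their share of all clinic
# users, and the derived total monthly headcount (= baseline / 0.306).
clinic,baseline_adolescents_per_month,baseline_uptake_share_pct,total_monthly_headcount
Clinic A,1531,30.60,5003
Clinic B,1808,30.60,5909
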