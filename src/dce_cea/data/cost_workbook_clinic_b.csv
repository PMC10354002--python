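# SYNTHETIC reconstruction of the Clinic B monthly cost workbook: the
# original clinic-level workbooks are not published line by line, so the
# category totals here are back-converted from published per-category USD
# aggregates (x14 ZAR) and the allocation rules follow the published
# costing assumptions. Amounts in 2019 ZAR per month. params holds
# 'name=value' pairs separated by ';' (gate = attribute(s) that must be in
# the scenario, joined by '|').
category,monthly_amount_zar,allocation_kind,params
assets,18009.04,none_incremental,
overheads,111865.46,shared_all_patients,
overheads,111865.46,extra_room_overhead,
staff_clinical,563202.92,afternoon_staff_time,
staff_nonclinical,213218.32,afternoon_staff_time,
supplies,6501.04,per_visit,unit_cost_zar=1.12
wifi,7250.00,fixed_monthly,gate=wifi
food,0,all_adolescents_billed_to_additional,unit_cost_zar=10
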