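{
  "clinic_profiles.csv": "5f269c38bcb04e99457fffe8c4b6a8b2f2b052495209a41e184e93cf6f7a6010",
  "coefficients.csv": "573c5489b7d3ebf0d9e8bdbe80dede80789e8fa755ed047e1f70277d35e31b26",
  "config.yaml": "21d931f79ba5db293d815b53fed70e2e3f2921eb74a4f2dfc770f769e3f60734",
  "cost_workbook_clinic_b.csv": "6d15eec0c1c8a9182e40d6393d7eed9d1532e47542ccb74f8b58821aba0326b5",
  "table1_uptake.csv": "2da90735eccf75ac4bbff2f7f3f4d2857027b37dee83a491fde4da598649aa88",
  "table2_clinic_a.csv": "94447d0b8eae9afe1b1e482b4824eb1481c3f1ee0e2759873784c0d7824366c8",
  "table3_clinic_b.csv": "ca0c52e55360083b83d12a5478c0f278e39082616b3d466cfca3f6ee56d0870c",
  "table_a3_clinic_a.csv": "e664b503907a2c628acbbdb96e9100076bb1018a602e510f54c9fe8b3c081ef1",
  "table_a4_clinic_b.csv": "37e0977bf106117ac58a200bd61eca233235bbf4a325700d389fbb1a91b283e2"
}
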