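{
  "mzrw_compounds.csv": "2f5ab52374c1fc852a6d1ab74c19b56d39910c061622427b68cd6dd3cddf7a89",
  "mzrw_group_members.csv": "2d899c8019ba690279c2fb20271e4d6b70aa4e15bef0046fe2d8b6fe24733f5f",
  "mzrw_representatives.csv": "ddf7f4445fb13679c4815a7350cd055cced130f6843b71e977fa9a431734ccc8",
  "mzrw_table1_predicted.csv": "cb2459867babfdcce4bee4cb6c7d6e18f892f0195a8f36a705c798d6129b25bc",
  "mzrw_table1_referenced.csv": "de860734876ddd5f0bef4266c5ea7508a6caf09bf198cc5c56771e078bfc2d61",
  "mzrw_table2_evidence.csv": "111ffc38bb2852e7b9e650b1bbd8a1103a822085b73985893495792bc19d36d3"
}
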