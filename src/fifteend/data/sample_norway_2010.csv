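variable,category,count
gender,men,1089
gender,women,1167
age_group,18-24,140
age_group,25-39,433
age_group,40-59,895
age_group,60-66,360
age_group,67+,428
education,elementary,472
education,high_school,960
education,university_ba,449
education,university_ma,318
education,no_formal,57
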