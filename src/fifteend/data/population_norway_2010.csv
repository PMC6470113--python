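variable,category,count
gender,men,1956835
gender,women,1981012
age_group,18-24,575921
age_group,25-39,985937
age_group,40-59,1331512
age_group,60-66,398529
age_group,67+,645948
education,elementary,1111379
education,high_school,1625640
education,university_ba,811360
education,university_ma,269627
education,no_formal,119841
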