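level,mobility,vision,hearing,breathing,sleep,eating,speech,elimination,usual_activities,mental_function,discomfort,depression,distress,vitality,sexual_activity
level_2,0.0357,0.0300,0.0304,0.0367,0.0327,0.0392,0.0386,0.0388,0.0331,0.0413,0.0382,0.0390,0.0367,0.0369,0.0297
level_3,0.0612,0.0625,0.0583,0.0612,0.0524,0.0721,0.0603,0.0729,0.0612,0.0687,0.0689,0.0625,0.0589,0.0569,0.0637
level_4,0.0876,0.0839,0.0830,0.0825,0.0774,0.0952,0.0847,0.0915,0.0831,0.0894,0.0899,0.0878,0.0831,0.0805,0.0849
level_5,0.1083,0.1012,0.0959,0.1008,0.0968,0.1061,0.0960,0.1038,0.1016,0.1022,0.1063,0.1039,0.0978,0.0976,0.0975
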