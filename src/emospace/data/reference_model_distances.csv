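,anger,fear,sadness,happiness,disgust,hope,love,hate,contempt,guilt,compassion,shame,gratefulness,envy,disappointment,jealousy
anger,0.0,0.324,0.761,1.114,0.891,1.199,0.932,0.84,1.081,1.078,1.294,0.842,1.315,1.115,0.802,0.607
fear,0.324,0.0,0.532,1.298,0.715,1.307,1.146,0.594,0.85,0.898,1.237,0.781,1.356,0.958,0.575,0.656
sadness,0.761,0.532,0.0,1.49,0.929,1.246,1.284,0.702,0.781,0.529,1.066,0.472,1.312,0.99,0.267,1.057
happiness,1.114,1.298,1.49,0.0,1.292,0.683,0.434,1.378,1.413,1.372,1.011,1.244,0.674,1.216,1.356,0.915
disgust,0.891,0.715,0.929,1.292,0.0,1.441,1.366,0.256,0.44,0.935,1.087,1.156,1.236,0.411,0.746,0.538
hope,1.199,1.307,1.246,0.683,1.441,0.0,0.501,1.411,1.363,1.037,0.699,0.842,0.484,1.269,1.142,1.237
love,0.932,1.146,1.284,0.434,1.366,0.501,0.0,1.379,1.439,1.251,1.028,0.971,0.776,1.326,1.217,0.994
hate,0.84,0.594,0.702,1.378,0.256,1.411,1.379,0.0,0.321,0.751,1.042,0.986,1.254,0.467,0.528,0.673
contempt,1.081,0.85,0.781,1.413,0.44,1.363,1.439,0.321,0.0,0.607,0.854,0.993,1.137,0.308,0.541,0.88
guilt,1.078,0.898,0.529,1.372,0.935,1.037,1.251,0.751,0.607,0.0,0.623,0.519,0.972,0.763,0.341,1.143
compassion,1.294,1.237,1.066,1.011,1.087,0.699,1.028,1.042,0.854,0.623,0.0,0.844,0.416,0.767,0.848,1.159
shame,0.842,0.781,0.472,1.244,1.156,0.842,0.971,0.986,0.993,0.519,0.844,0.0,1.024,1.103,0.504,1.141
gratefulness,1.315,1.356,1.312,0.674,1.236,0.484,0.776,1.254,1.137,0.972,0.416,1.024,0.0,0.968,1.119,1.135
envy,1.115,0.958,0.99,1.216,0.411,1.269,1.326,0.467,0.308,0.763,0.767,1.103,0.968,0.0,0.737,0.763
disappointment,0.802,0.575,0.267,1.356,0.746,1.142,1.217,0.528,0.541,0.341,0.848,0.504,1.119,0.737,0.0,0.934
jealousy,0.607,0.656,1.057,0.915,0.538,1.237,0.994,0.673,0.88,1.143,1.159,1.141,1.135,0.763,0.934,0.0
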