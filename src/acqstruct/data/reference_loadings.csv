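facet,framing,pole,corrected_O,corrected_C,corrected_E,corrected_A,corrected_N,raw_O,raw_C,raw_E,raw_A,raw_N
artistic_interest,identity_neg,-,0.426,0.079,0.046,0.316,-0.132,0.229,0.25,0.261,0.468,-0.092
artistic_interest,identity_pos,+,0.589,-0.062,-0.038,0.123,-0.016,0.595,0.037,0.009,-0.002,0.02
artistic_interest,self_efficacy,+,0.724,0.0,-0.175,-0.033,0.128,0.729,0.042,-0.155,0.136,0.098
creative_imagination,identity_neg,-,0.473,0.029,0.17,0.106,-0.137,0.338,0.093,0.305,0.438,-0.112
creative_imagination,identity_pos,+,0.703,-0.04,0.15,-0.1,-0.05,0.76,-0.075,0.098,-0.039,-0.02
creative_imagination,self_efficacy,+,0.812,0.021,-0.006,-0.11,0.121,0.85,-0.003,-0.022,0.106,0.089
curiosity_to_learn,identity_neg,-,0.351,0.021,0.107,0.263,-0.177,0.175,0.165,0.295,0.399,-0.152
curiosity_to_learn,identity_pos,+,0.448,0.066,0.143,0.183,-0.114,0.483,0.158,0.16,-0.184,-0.056
curiosity_to_learn,self_efficacy,+,0.562,0.169,0.049,0.07,0.123,0.59,0.214,0.071,-0.02,0.105
determination,identity_neg,-,0.149,0.36,0.106,0.086,-0.132,0.037,0.339,0.203,0.428,-0.105
determination,identity_pos,+,0.018,0.797,-0.011,0.006,-0.079,0.149,0.709,-0.087,-0.114,-0.028
determination,self_efficacy,+,0.168,0.493,0.148,0.069,0.132,0.244,0.481,0.103,-0.208,0.127
focus,identity_neg,-,0.205,0.524,-0.103,-0.047,0.022,0.113,0.431,-0.042,0.553,0.039
focus,identity_pos,+,0.078,0.56,-0.046,0.032,0.046,0.194,0.493,-0.113,-0.143,0.093
focus,self_efficacy,+,0.182,0.574,-0.11,-0.059,0.253,0.258,0.508,-0.191,-0.054,0.24
organization,identity_neg,-,-0.149,0.727,-0.027,0.01,0.003,-0.182,0.644,-0.015,0.297,0.04
organization,identity_pos,+,-0.139,0.867,-0.031,-0.014,-0.02,0.007,0.752,-0.131,-0.157,0.026
organization,self_efficacy,+,-0.051,0.75,-0.063,-0.047,0.183,0.047,0.669,-0.161,-0.122,0.175
persistence,identity_neg,-,0.013,0.716,0.016,0.103,-0.191,-0.052,0.7,0.086,0.336,-0.144
persistence,identity_pos,+,0.007,0.673,0.124,0.033,-0.046,0.145,0.585,0.033,-0.236,0.01
persistence,self_efficacy,+,0.165,0.68,-0.074,-0.063,0.099,0.253,0.62,-0.15,-0.043,0.079
responsibility,identity_neg,-,-0.008,0.459,0.173,0.214,-0.126,-0.108,0.493,0.28,0.299,-0.075
responsibility,identity_pos,+,-0.042,0.53,0.123,0.265,-0.1,0.039,0.599,0.128,-0.283,-0.033
responsibility,self_efficacy,+,0.029,0.456,0.037,0.268,0.085,0.049,0.583,0.08,-0.211,0.088
enthusiasm,identity_neg,-,0.079,-0.074,0.534,0.052,-0.041,0.007,-0.1,0.575,0.204,-0.021
enthusiasm,identity_pos,+,-0.017,0.063,0.584,0.06,0.221,0.12,-0.025,0.467,-0.36,0.264
enthusiasm,self_efficacy,+,0.08,0.236,0.3,0.137,0.322,0.142,0.232,0.279,-0.241,0.329
assertiveness,identity_neg,-,0.195,0.126,0.445,-0.207,0.01,0.158,-0.052,0.4,0.327,-0.004
assertiveness,identity_pos,+,0.261,0.139,0.351,-0.188,-0.123,0.402,0.004,0.192,-0.288,-0.096
assertiveness,self_efficacy,+,0.189,0.381,0.191,-0.13,0.179,0.288,0.255,0.093,-0.088,0.158
social_initiative,identity_neg,-,0.052,-0.181,0.607,-0.073,0.023,0.015,-0.263,0.587,0.086,0.013
social_initiative,identity_pos,+,-0.05,-0.078,0.649,0.223,0.014,0.055,-0.045,0.605,-0.506,0.051
social_initiative,self_efficacy,+,0.059,0.072,0.316,0.05,0.259,0.132,0.052,0.252,-0.333,0.243
empathy,identity_neg,-,0.148,0.074,0.215,0.451,-0.141,-0.021,0.299,0.423,0.255,-0.078
empathy,identity_pos,+,0.053,-0.022,0.217,0.54,-0.013,0.063,0.243,0.309,-0.401,0.051
empathy,self_efficacy,+,0.245,0.039,0.184,0.388,-0.006,0.237,0.263,0.279,-0.321,-0.011
gratitude,identity_neg,-,0.036,0.064,-0.109,0.615,-0.083,-0.184,0.375,0.185,0.33,-0.034
gratitude,identity_pos,+,0.05,-0.093,-0.199,0.346,-0.045,0.041,0.129,-0.101,-0.202,0.01
gratitude,self_efficacy,+,0.187,0.124,-0.175,0.318,0.249,0.161,0.313,-0.091,-0.135,0.248
respect,identity_neg,-,0.031,0.299,-0.216,0.457,0.138,-0.153,0.492,0.019,0.438,0.184
respect,identity_pos,+,-0.016,0.366,-0.025,0.508,-0.017,-0.013,0.593,0.107,-0.158,0.056
respect,self_efficacy,+,0.136,0.166,-0.168,0.437,0.353,0.084,0.402,-0.043,-0.087,0.375
trust,identity_neg,-,-0.011,-0.007,0.128,0.087,0.267,-0.126,-0.011,0.201,0.381,0.266
trust,identity_pos,+,-0.002,-0.117,0.202,0.326,0.187,0.04,0.022,0.22,-0.341,0.232
trust,self_efficacy,+,0.069,-0.129,0.123,0.173,0.347,0.088,-0.055,0.124,-0.229,0.347
frustration_tolerance,identity_neg,-,0.046,-0.041,-0.023,0.176,0.586,-0.108,-0.033,0.094,0.545,0.64
frustration_tolerance,identity_pos,+,-0.036,-0.06,-0.081,0.137,0.527,0.0,-0.051,-0.101,-0.057,0.601
frustration_tolerance,self_efficacy,+,0.071,-0.074,-0.124,0.205,0.747,0.031,-0.004,-0.094,0.027,0.789
stress_modulation,identity_neg,-,0.031,0.085,0.193,-0.189,0.444,-0.031,-0.113,0.164,0.484,0.434
stress_modulation,identity_pos,+,0.046,0.102,0.214,-0.033,0.397,0.166,-0.003,0.086,-0.227,0.428
stress_modulation,self_efficacy,+,0.11,0.034,-0.028,0.033,0.739,0.128,-0.001,-0.081,-0.035,0.751
self_confidence,identity_neg,-,-0.127,0.238,0.294,0.009,0.349,-0.183,0.095,0.306,0.403,0.354
self_confidence,identity_pos,+,-0.068,0.134,0.291,0.126,0.3,0.041,0.09,0.217,-0.256,0.368
self_confidence,self_efficacy,+,0.068,0.169,0.254,0.09,0.496,0.123,0.137,0.206,-0.21,0.502
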