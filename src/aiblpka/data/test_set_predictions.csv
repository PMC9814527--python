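id,pka_exp,CO,PLS,RFR,SVR_linear,SVR_rbf,GPR_rbf,Marvin_taut,Marvin_no_taut
tk1,1.56,2.48,2.28,2.71,2.66,2.34,3.16,2.44,2.44
tk8,2.84,3.33,3.45,2.78,3.40,3.39,2.88,4.35,4.35
tkc6,3.20,3.34,3.45,2.79,3.41,3.39,2.87,3.73,3.73
tet2,3.48,3.52,3.63,2.83,3.58,3.54,3.01,2.63,2.99
tet4,3.50,3.42,3.45,2.91,3.48,3.40,2.99,2.19,2.95
tkc2,3.83,4.08,4.17,4.41,4.05,4.09,4.07,4.29,4.29
dk25,3.85,3.69,3.29,2.86,3.72,3.26,3.21,8.17,7.87
dk26,3.92,3.85,3.59,3.35,3.85,3.55,4.27,9.18,8.70
o6,4.30,4.64,4.75,4.82,4.52,4.69,5.11,16.34,5.30
o3,4.34,4.64,4.74,4.73,4.52,4.69,5.09,17.00,5.47
o7,4.35,4.70,4.83,4.92,4.56,4.76,5.14,17.15,5.73
o4,4.47,4.53,4.66,4.58,4.43,4.58,5.05,16.09,5.79
o2,4.51,4.63,4.73,4.79,4.52,4.67,5.08,16.06,5.70
dk6,4.62,4.62,4.75,4.56,4.50,4.63,4.57,6.44,5.31
dk10,4.71,4.79,4.83,4.36,4.62,4.76,4.35,8.14,5.17
dk19,4.76,4.77,4.63,4.75,4.66,4.66,4.76,8.76,5.66
dk5,5.06,5.17,5.26,5.17,4.94,5.21,5.09,8.90,6.50
dk15,5.08,4.87,4.81,4.98,4.74,4.82,4.98,7.83,6.54
dk7,5.10,4.69,4.82,4.89,4.55,4.71,4.73,8.46,5.19
dk12,5.16,5.02,5.11,5.19,4.80,5.05,4.84,7.88,5.85
dk21,5.19,4.89,4.87,4.98,4.77,4.84,5.02,8.11,6.61
dk8,5.69,4.92,5.18,5.16,4.76,5.01,5.24,8.35,5.93
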