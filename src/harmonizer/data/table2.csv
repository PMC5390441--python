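target,unit,construction_sensitivity,construction_specificity,construction_ppv,construction_npv,validation_sensitivity,validation_specificity,validation_ppv,validation_npv
Age,years,1.0,0.997549,0.78,1.0,0.956522,0.994545,0.511628,0.999739
BMI,kg/m2,0.973684,0.999777,0.973684,0.999777,0.454545,0.998958,0.789474,0.99533
Urea,mg/dl,1.0,0.78333,0.004065,1.0,1.0,0.822693,0.005797,1.0
Cholesterol,mg/dl,0.913043,0.999778,0.954545,0.999556,0.588235,1.0,1.0,0.998188
Cholesterol SI,mmol/l,0.956522,0.463366,0.00902,0.999521,0.375,0.443609,0.002788,0.994189
Creatinine,mg/dl,0.947368,0.727595,0.014446,0.999695,0.777778,0.825311,0.010264,0.999373
Diabetes,-,1.0,0.005797,0.009331,1.0,0.757576,0.015625,0.00657,0.882353
Education,-,0.866667,0.499778,0.005727,0.999114,0.888889,0.508799,0.004197,0.999492
Ethnicity,-,0.916667,0.998671,0.647059,0.999778,0.625,0.998706,0.5,0.999223
Event date,-,0.771084,0.455221,0.025755,0.990695,0.580645,0.407407,0.02354,0.975301
Fasting glucose,mg/dl,0.954545,0.980022,0.189189,0.999774,0.5625,0.994555,0.3,0.998179
Fasting glucose SI,mmol/l,1.0,0.015289,0.00314,1.0,0.866667,0.020477,0.003428,0.975309
Fibrinogen,mg/dl,0.928571,0.515622,0.005912,0.99957,1.0,0.556648,0.004067,1.0
Hemoglobin,g/dl,0.923077,0.145104,0.0031,0.998476,0.875,0.124191,0.002064,0.997921
Hemoglobin SI,g/l,1.0,0.024326,0.001132,1.0,0.0,0.047065,0.0,0.968085
Hba1c,%,0.944444,0.999113,0.809524,0.999778,0.666667,1.0,1.0,0.998965
HDL cholesterol,mg/dl,0.35,0.999334,0.7,0.997122,0.1875,0.998704,0.375,0.996636
HDL cholesterol SI,mmol/l,0.863636,0.978246,0.162393,0.99932,0.705882,0.977178,0.12,0.998675
History of CVD,-,0.611111,0.98368,0.311321,0.99525,0.348485,0.967923,0.277108,0.976801
Hs-CRP,mg/l,0.875,0.99823,0.466667,0.999778,1.0,0.998702,0.807692,1.0
Hypertension,-,0.941176,0.971511,0.2,0.999542,0.965517,0.961238,0.158192,0.999729
Intima Media Thickness (IMT),0.1 mm,0.73494,0.0,0.013541,0.0,0.99115,0.0,0.057866,0.0
Intima Media Thickness (IMT) SI,mm,0.354911,0.989703,0.791045,0.933195,0.070588,0.969044,0.138462,0.936682
Arterial diameter,mm,0.685393,0.989184,0.559633,0.993662,0.509259,0.998406,0.901639,0.986097
Income,-,1.0,0.0,0.000884,0.0,1.0,0.0,0.000516,0.0
LDL cholesterol,mg/dl,0.0,1.0,0.0,0.995582,0.0,1.0,0.0,0.996902
LDL cholesterol SI,mmol/l,0.73913,0.992451,0.333333,0.99866,0.5,0.996368,0.391304,0.997662
Leukocytes,1/ul,0.0,0.993803,0.0,0.998,0.0,0.997411,0.0,0.997152
Dyslipidemia,-,0.923077,0.999335,0.8,0.999778,0.416667,0.998446,0.454545,0.998187
Antidiabetic medication,-,0.761905,0.997074,0.831169,0.995506,0.571429,0.998688,0.878049,0.992954
Antihypertensive medication,-,0.989362,0.591699,0.04887,0.999619,0.886364,0.607057,0.073724,0.993438
Lipid-lowering medication,-,0.987179,0.510227,0.034131,0.99956,0.982143,0.5093,0.028527,0.999486
Nicotine consumption,Pack years,0.8,1.0,1.0,0.998891,0.714286,0.999482,0.833333,0.998964
Carotid plaque,-,0.613636,0.999108,0.870968,0.996219,0.953757,1.0,1.0,0.997843
Diastolic blood pressure,mmHg,0.965116,0.985364,0.560811,0.999315,0.764706,0.983255,0.378641,0.996817
Systolic blood pressure,mmHg,0.674419,0.999775,0.983051,0.993733,0.510638,0.996602,0.648649,0.994004
Socioeconomic status,-,1.0,0.076514,0.004304,1.0,0.888889,0.072205,0.002227,0.996429
Sex,-,0.875,0.999334,0.875,0.999334,0.6875,0.998444,0.647059,0.998703
Smoking status,-,0.972603,0.20229,0.019592,0.997785,0.75,0.26145,0.013632,0.987154
Triglycerides,mg/dl,0.969697,0.136849,0.008182,0.998377,0.0,0.077201,0.0,1.0
Ultrasound date,-,0.0,0.999553,0.0,0.988729,0.0,1.0,0.988897,1.0
Average,,0.799584,0.707405,0.34172,0.947871,0.619019,0.710383,0.325339,0.941999
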