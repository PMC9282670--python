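item_id,text,overall_difficulty,step1,step2,step3,step4
1,Gender (male as 1 and female as 0),0.16,0.00,NA,NA,NA
2,Skin color on areas never exposed to the sun?,-2.32,-2.46,0.78,1.68,NA
3,Your behavior in the strong sun for 30 minutes at noon?,-0.17,-1.51,0.41,1.10,NA
4,Your behavior outdoors in the sun without protecting your skin?,-0.49,-0.85,-0.42,1.27,NA
5,What color are your eyes?,-0.11,-0.04,0.60,1.55,-2.11
6,What was your natural hair color at the age of 21 years?,0.48,0.70,-0.83,-1.30,1.43
7,How many freckles were on your face at the age of 21 years?,0.72,-0.37,0.01,0.36,NA
8,How many moles did you have on your skin at the age of 21 years?,0.76,-1.45,0.53,0.92,NA
9,How many times in your whole life have you used sunbeds?,1.27,1.35,0.30,-0.75,-0.69
10,How many separate skin cancers have you ever had excised from your skin?,0.98,0.45,-1.36,1.30,-0.39
11,How many separate sunspots or skin cancers have you ever had frozen or burnt off on your skin?,0.53,-0.05,0.49,-0.22,-0.11
12,Have I been told that I have melanoma?,0.99,0.99,NA,NA,NA
13,Will you get melanoma at some point in the future?,0.26,-1.14,-0.82,1.14,0.82
14,How many times were you sunburned so badly that you were sore for at least 2 days or your skin peeled as a child?,0.58,-1.41,0.37,0.11,0.36
15,How many times were you sunburned so badly that you were sore for at least 2 days or your skin peeled in your teenage years?,0.17,-2.40,0.35,0.27,0.74
16,How many times were you sunburned so badly that you were sore for at least 2 days or your skin peeled in adulthood?,0.58,-1.83,0.59,0.10,0.46
17,How many hours did you spend outdoors and in the sun from Monday to Friday in the past year?,0.29,-0.04,0.44,-0.39,NA
18,How many hours did you spend outdoors and in the sun from Monday to Friday at the age of 10 to 19 years?,-0.51,-0.65,0.24,0.41,NA
19,How many hours did you spend outdoors and in the sun from Monday to Friday at the age of 20 to 29 years?,-0.15,-0.46,0.41,0.05,NA
20,How many hours did you spend outdoors and in the sun from Monday to Friday at the age of 30 to 39 years?,0.04,-0.29,0.42,-0.13,NA
21,How many hours did you spend outdoors and in the sun during Saturday and Sunday in the past year?,-0.14,-0.42,0.23,0.19,NA
22,How many hours did you spend outdoors and in the sun during Saturday and Sunday at the age of 10 to 19 years?,-0.94,-0.46,0.21,0.26,NA
23,How many hours did you spend outdoors and in the sun during Saturday and Sunday at the age of 20 to 29 years?,-0.72,-0.60,0.18,0.43,NA
24,How many hours did you spend outdoors and in the sun during Saturday and Sunday at the age of 30 to 39 years?,-0.45,-0.56,0.19,0.37,NA
25,Routinely apply sunscreen to my face,-0.46,0.00,NA,NA,NA
26,Routinely apply sunscreen to my hands and forearms,-1.80,0.00,NA,NA,NA
27,Routinely apply sunscreen to other parts of my body,-2.56,0.00,NA,NA,NA
28,Routinely apply sunscreen going out in the sun: no,-0.36,0.00,NA,NA,NA
29,Whether applying sunscreen outside in the sun?,-0.31,-0.90,-0.16,1.06,NA
30,How often have you been outside in the sun in the past year?,0.45,-0.77,-0.08,0.85,NA
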