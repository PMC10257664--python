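term,group,any_grade_count,ge3_count
anemia,none,2,2
anemia,low,3,1
anemia,high,3,0
lymphopenia,none,0,0
lymphopenia,low,3,3
lymphopenia,high,3,3
leukopenia,none,1,0
leukopenia,low,2,0
leukopenia,high,3,0
neutropenia,none,1,0
neutropenia,low,3,0
neutropenia,high,2,0
leukocytosis,none,1,0
neutrophilia,none,1,0
thrombocytopenia,high,1,0
hyperuricemia,high,1,0
pruritus,none,1,0
pruritus,low,3,0
pruritus,high,1,0
rash,none,1,0
rash,low,2,0
herpes zoster,low,1,0
herpes zoster,high,1,0
skin infection,low,1,1
stomatitis,low,1,0
fever,none,1,0
acute bronchitis,high,1,0
cough,none,2,0
cough,low,1,0
cough,high,1,0
immune associated pneumonia,none,1,0
immune associated pneumonia,high,1,0
sinus tachycardia,low,2,0
sinus tachycardia,high,2,0
gastrointestinal reaction,none,1,0
gastrointestinal reaction,low,1,0
gastrointestinal reaction,high,2,0
impaired liver function,none,2,0
impaired liver function,low,1,0
impaired liver function,high,1,0
creatinine increased,none,1,0
creatinine increased,high,1,0
CPK increased,none,2,0
cystatin C increased,none,1,0
cystatin C increased,low,1,0
cystatin C increased,high,2,0
proteinuria,none,2,0
proteinuria,low,2,0
proteinuria,high,2,0
hypoalbuminemia,none,2,0
hypoalbuminemia,low,3,0
hypoalbuminemia,high,3,0
total bilirubin increased,high,2,1
direct bilirubin increased,high,1,1
urobilinogen increased,none,2,0
urobilinogen increased,high,1,0
increased urine sediment mucus count,none,1,0
increased urine sediment mucus count,low,1,0
increased urine sediment mucus count,high,2,0
urine occult blood,none,1,0
urine occult blood,low,3,0
urine occult blood,high,1,0
fecal occult blood,none,2,0
fecal occult blood,low,1,1
fecal occult blood,high,1,0
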