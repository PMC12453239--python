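variable,level,fri,control,printed_p
Sex,Male,10,6,0.226
Sex,Female,3,7,0.226
Implant Used,IMN,9,3,0.047
Implant Used,Plate,4,10,0.047
Fracture Type,Open,4,0,0.096
Fracture Type,Closed,9,13,0.096
NSAID/Steroid Use,Yes,1,0,>0.999
NSAID/Steroid Use,No,12,13,>0.999
Diabetes Mellitus,Yes,1,4,0.322
Diabetes Mellitus,No,12,9,0.322
History of MRSA,Yes,2,0,0.48
History of MRSA,No,11,13,0.48
Tobacco Use,Yes,4,3,>0.999
Tobacco Use,No,9,10,>0.999
Alcohol Abuse,Yes,2,0,0.48
Alcohol Abuse,No,11,13,0.48
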