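error_code,error_name,category,attribute,mu_lo,mu_hi,nu_lo,nu_hi
L18,Clotted sample,Laboratory,severity,0.472,0.572,0.277,0.428
L18,Clotted sample,Laboratory,preventability,0.553,0.654,0.193,0.346
L17,Sample with hemolysis,Laboratory,severity,0.485,0.585,0.264,0.415
L17,Sample with hemolysis,Laboratory,preventability,0.555,0.656,0.19,0.344
L16,Insufficient sample,Laboratory,severity,0.466,0.57,0.281,0.43
L16,Insufficient sample,Laboratory,preventability,0.586,0.687,0.16,0.313
L05,Wrong record,Laboratory,severity,0.432,0.55,0.303,0.45
L05,Wrong record,Laboratory,preventability,0.559,0.66,0.188,0.34
L01,Wrong test request,Laboratory,severity,0.415,0.53,0.328,0.47
L01,Wrong test request,Laboratory,preventability,0.618,0.718,0.13,0.282
I1g,Erroneous dosing,Medication,severity,0.537,0.637,0.211,0.363
I1g,Erroneous dosing,Medication,preventability,0.511,0.619,0.227,0.382
I1a,Wrong drug demand,Medication,severity,0.505,0.605,0.244,0.395
I1a,Wrong drug demand,Medication,preventability,0.533,0.636,0.212,0.364
I0a,Inappropriate temperature and humidity,Medication,severity,0.41,0.528,0.331,0.472
I0a,Inappropriate temperature and humidity,Medication,preventability,0.56,0.7,0.147,0.3
I2b,Preparation of wrong drug,Medication,severity,0.538,0.643,0.202,0.357
I2b,Preparation of wrong drug,Medication,preventability,0.527,0.631,0.217,0.369
I3c,Transferring wrong drug from pharmacy,Medication,severity,0.486,0.59,0.259,0.41
I3c,Transferring wrong drug from pharmacy,Medication,preventability,0.566,0.667,0.181,0.333
di,Non-marking of operation area/side,General/Surgical,severity,0.551,0.651,0.197,0.349
di,Non-marking of operation area/side,General/Surgical,preventability,0.554,0.658,0.183,0.342
kd,"Unverified patient ID, location of operation and surgical procedure",General/Surgical,severity,0.529,0.63,0.219,0.37
kd,"Unverified patient ID, location of operation and surgical procedure",General/Surgical,preventability,0.558,0.663,0.18,0.337
gd,"Not confirming removal of make-up, prosthesis and valuable items",General/Surgical,severity,0.483,0.585,0.264,0.415
gd,"Not confirming removal of make-up, prosthesis and valuable items",General/Surgical,preventability,0.576,0.682,0.16,0.318
tr,The operation area has not been shaved,General/Surgical,severity,0.491,0.595,0.254,0.406
tr,The operation area has not been shaved,General/Surgical,preventability,0.591,0.696,0.146,0.304
ts,Health worker does not accompany patient transfer,General/Surgical,severity,0.482,0.582,0.267,0.418
ts,Health worker does not accompany patient transfer,General/Surgical,preventability,0.572,0.678,0.166,0.322
HRHc,Patient falls,Patient Related,severity,0.596,0.697,0.146,0.303
HRHc,Patient falls,Patient Related,preventability,0.543,0.645,0.199,0.356
TKHg,Incorrect report of patient basic information,Patient Related,severity,0.531,0.631,0.217,0.369
TKHg,Incorrect report of patient basic information,Patient Related,preventability,0.566,0.671,0.175,0.329
TKHa,Incorrect identification of patients,Patient Related,severity,0.582,0.684,0.157,0.316
TKHa,Incorrect identification of patients,Patient Related,preventability,0.547,0.656,0.186,0.344
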