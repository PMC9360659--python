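department,day_hospital_beds,hospitalization_beds
CARDIOLOGY,2,24
GENERAL SURGERY,8,139
MAXILLO FACIAL SURGERY,2,14
PAEDIATRIC SURGERY,2,8
PLASTIC SURGERY,2,12
THORACIC SURGERY,1,10
VASCULAR SURGERY,2,14
HEMATOLOGY,24,35
GENERAL MEDICINE,11,165
NEPHROLOGY,1,7
NEUROSURGERY,2,58
NEUROLOGY,4,27
OPHTHALMOLOGY,4,14
ORTHOPEDICS AND TRAUMATOLOGY,7,77
OBSTETRICS AND GYNECOLOGY,7,40
ENT,2,16
PAEDIATRICS,10,32
TOXICOLOGY,0,4
UROLOGY,4,24
BURN UNIT,0,15
INTENSIVE CARE,2,30
CORONARY UNIT,0,18
CASUALTY DEPARTMENT,0,40
DERMATOLOGY,2,10
RECOVERY AND FUNCTIONAL REHABILITATION,2,13
GASTROENTEROLOGY,3,32
ONCOLOGY,10,21
PNEUMOLOGY,6,34
NEONATAL INTENSIVE CARE,2,17
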