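category,hepatitis,treatment,outcome,count
ALF_WITHOUT_COMA,true,medical_only,survived,72
ALF_WITHOUT_COMA,true,medical_only,died,11
ALF_WITHOUT_COMA,true,transplant,transplanted_alive,2
ALF_WITHOUT_COMA,true,transplant,transplanted_dead,0
ALF_WITH_COMA_ACUTE,true,medical_only,survived,13
ALF_WITH_COMA_ACUTE,true,medical_only,died,28
ALF_WITH_COMA_ACUTE,true,transplant,transplanted_alive,8
ALF_WITH_COMA_ACUTE,true,transplant,transplanted_dead,5
ALF_WITH_COMA_SUBACUTE,true,medical_only,survived,7
ALF_WITH_COMA_SUBACUTE,true,medical_only,died,29
ALF_WITH_COMA_SUBACUTE,true,transplant,transplanted_alive,7
ALF_WITH_COMA_SUBACUTE,true,transplant,transplanted_dead,6
LOHF,true,medical_only,survived,0
LOHF,true,medical_only,died,8
LOHF,true,transplant,transplanted_alive,1
LOHF,true,transplant,transplanted_dead,0
ALF_WITHOUT_COMA,false,medical_only,survived,5
ALF_WITHOUT_COMA,false,medical_only,died,6
ALF_WITH_COMA_ACUTE,false,medical_only,survived,1
ALF_WITH_COMA_ACUTE,false,medical_only,died,6
ALF_WITH_COMA_SUBACUTE,false,medical_only,survived,0
ALF_WITH_COMA_SUBACUTE,false,medical_only,died,5
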