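category,etiology_group,count
ALF_WITHOUT_COMA,viral,43
ALF_WITHOUT_COMA,indeterminate,27
ALF_WITHOUT_COMA,other_hepatitis,15
ALF_WITHOUT_COMA,non_hepatitis,11
ALF_WITH_COMA_ACUTE,viral,29
ALF_WITH_COMA_ACUTE,indeterminate,17
ALF_WITH_COMA_ACUTE,other_hepatitis,8
ALF_WITH_COMA_ACUTE,non_hepatitis,7
ALF_WITH_COMA_SUBACUTE,viral,19
ALF_WITH_COMA_SUBACUTE,indeterminate,22
ALF_WITH_COMA_SUBACUTE,other_hepatitis,8
ALF_WITH_COMA_SUBACUTE,non_hepatitis,5
LOHF,viral,3
LOHF,indeterminate,2
LOHF,other_hepatitis,4
LOHF,non_hepatitis,0
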