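patient_id,group,pct_small,pct_large,n_small,n_large,pro_swmri
RN1,radionecrosis,91,9,50,4,28
RN2,radionecrosis,46,54,36,45,69
RN3,radionecrosis,53,47,42,37,76
RN4,radionecrosis,40,60,6,9,79
RN5,radionecrosis,71,29,5,2,80
RN6,radionecrosis,45,55,11,13,88
RN7,radionecrosis,52,48,15,14,88
RC1,recurrence,100,0,21,0,0
RC2,recurrence,100,0,2,0,0
RC3,recurrence,100,0,39,0,0
RC4,recurrence,100,0,4,0,0.1
RC5,recurrence,100,0,4,0,1
RC6,recurrence,100,0,8,0,5
RC7,recurrence,91,9,10,1,7
RC8,recurrence,88,12,28,6,7
RC9,recurrence,79,21,15,8,7
RC10,recurrence,79,21,15,8,13
RC11,recurrence,92,8,26,5,17
RC12,recurrence,95,5,77,6,31
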