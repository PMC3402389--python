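study_id,first_author,year,ethnicity,control_source,method,case_gg,case_gt,case_tt,ctrl_gg,ctrl_gt,ctrl_tt
Hu,Hu,2006,Asian,HB,PIRA-PCR,178,373,166,271,538,274
Li,Li,2006,Caucasian,HB,PIRA-PCR,135,472,419,164,573,408
Lind,Lind,2006,Caucasian,PB,TaqMan,55,156,130,44,207,161
Park,Park,2006,Asian,HB,PCR-RFLP,189,280,113,161,299,122
Pine(African),Pine,2006,African,HB,MGB Eclipse,2,20,111,5,47,203
Pine(Caucasian),Pine,2006,Caucasian,HB,MGB Eclipse,54,167,150,52,187,182
Zhang,Zhang,2006,Asian,PB,ARMS-PCR,296,561,249,291,711,418
Liu,Liu,2008,Caucasian,HB,TaqMan,283,802,702,199,631,530
Mittelstrass,Mittelstrass,2008,Caucasian,PB,MALDI-TOF,70,293,270,149,598,547
Chua,Chua,2010,Asian,HB,Sequencing,29,65,29,51,83,25
Kohno,Kohno,2011,Asian,HB,Pyrosequencing,126,183,68,95,151,79
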