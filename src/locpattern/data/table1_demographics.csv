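subject,onset_age,testing_age
IAG,0,56.25
IBA,0,74.92
IBN,0,64.92
ICW,0,21.33
IDD,0.5,18.17
IDF,1,18.75
ICG,2,50.08
ICH,2,32.42
ICZ,2.5,20.83
IAU,3,66.75
ICD,3,54.42
ICL,3,45.42
ICQ,3.83,19.25
ICO,4,32.83
ICP,4,50.67
IAJ,5,66.17
IBJ,8,30.67
ICX,8,74.42
IDA,8,48.67
ICC,9,66.75
ICN,10,40
ICA,13,52.25
IDB,17.5,71.33
ICT,18.5,21.33
ICB,22,61.92
IBO,23,47.25
ICM,23,59.5
ICJ,25,63.42
IDC,26,64.67
ICR,27,59.75
IBR,28,57.42
ICI,31,54.5
IBD,33,82.25
ICF,35,70.33
IDE,35,70.58
IBM,36,57.5
IBF,38,63.67
IBZ,38,44.17
IBY,41,48.92
ICV,43,58.42
IBX,46,70.5
IBK,53,72.25
IAZ,55,81.08
IBP,55,62.67
IBQ,57,81
ICK,57,69.67
ICE,66,72.83
ICS,68,85.92
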