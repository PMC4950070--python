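study_id,followup_months,NmE,RmE,SEmE,NmC,RmC,SEmC,NrE,ARrE,NrC,ARrC,NdE,RdE,NdC,RdC
Paty (A),24,124,1.80,0.40,124,4.9,1.30,124,145,124,157,124,35,124,35
Paty (B),24,124,2.00,0.70,124,4.9,1.30,124,104,124,157,124,25,124,35
Jacobs,24,85,3.20,0.41,87,4.8,0.49,85,52,87,78,85,18,87,29
Millefiorini,24,23,3.50,0.71,19,7.3,1.84,27,12,24,31,27,2,24,9
Li (C),24,189,9.00,4.00,187,15.5,2.90,189,172,187,240,189,57,187,69
Li (D),24,184,5.50,0.50,187,15.5,2.90,184,159,187,240,184,50,187,69
Polman,24,627,1.90,0.37,315,11.0,0.88,627,144,315,230,627,107,315,91
Comi (E),24,433,0.38,0.07,437,1.43,0.06,433,61,437,144,433,62,437,90
Comi (F),24,456,0.33,0.06,437,1.43,0.06,456,68,437,144,456,69,437,90
Rudick,24,589,0.90,0.09,582,5.4,0.36,589,200,582,437,589,135,582,169
Sorensen,24,66,2.70,0.46,64,3.5,0.51,66,15,64,38,66,11,64,16
Clanet,36,400,8.00,0.88,402,9.0,0.74,400,324,402,310,400,148,402,149
Mikol,24,172,0.58,0.11,178,0.77,0.18,386,116,378,110,386,45,378,33
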