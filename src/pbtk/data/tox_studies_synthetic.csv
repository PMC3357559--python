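study_id,dose_mg_per_kg_day,duration_weeks,administration,grade
S01,2.3,104,dietary,0
S01,15.0,104,dietary,0
S01,70.0,104,dietary,1
S02,25.0,52,gavage,2
S02,100.0,52,gavage,3
S03,10.0,13,dietary,0
S03,50.0,13,dietary,1
S03,200.0,13,dietary,2
S04,30.0,4,gavage,2
S04,90.0,4,gavage,3
S04,300.0,4,gavage,4
S05,5.0,26,dietary,0
S05,35.0,26,dietary,1
S05,150.0,26,dietary,1
S06,12.5,13,gavage,2
S06,50.0,13,gavage,3
S06,200.0,13,gavage,4
S06,535.0,13,gavage,4
S07,20.0,52,dietary,0
S07,80.0,52,dietary,1
S08,60.0,26,gavage,3
S08,180.0,26,gavage,4
S08,450.0,26,gavage,4
S09,100.0,4,gavage,3
S09,333.0,4,gavage,4
S09,535.0,4,gavage,4
S10,8.0,104,gavage,1
S10,40.0,104,gavage,3
S10,160.0,104,gavage,4
S11,300.0,13,dietary,2
S11,500.0,13,dietary,2
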