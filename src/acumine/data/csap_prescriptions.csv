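study_id,acupoint
S01,LU6
S01,LU9
S01,HT5
S01,PC6
S01,ST40
S02,LU6
S02,LU9
S02,HT5
S02,PC6
S02,RN17
S03,LU6
S03,LU9
S03,HT5
S03,PC6
S03,RN4
S04,LU6
S04,LU9
S04,HT5
S04,PC6
S04,KI3
S05,LU6
S05,LU9
S05,PC6
S05,LR3
S05,SP6
S05,LI4
S06,HT5
S06,PC6
S06,LR3
S06,BL20
S06,RN6
S06,HT1
S07,LU9
S07,PC6
S07,BL15
S07,SP10
S08,LU9
S08,PC6
S08,BL15
S08,SP8
S09,LU9
S09,PC6
S09,BL15
S09,SP9
S10,LU9
S10,PC6
S10,BL15
S10,BL13
S11,LU9
S11,PC6
S11,HT7
S11,LU1
S12,LU9
S12,PC6
S12,HT7
S12,RN12
S13,LU9
S13,PC6
S13,HT7
S13,LU7
S14,LU9
S14,PC6
S14,BL14
S14,BL17
S14,ST40
S14,RN14
S15,LU9
S15,PC6
S15,BL14
S15,BL17
S15,RN17
S15,PC4
S16,LU9
S16,PC6
S16,BL14
S16,BL17
S16,RN4
S16,PC4
S17,LU9
S17,BL14
S17,LI11
S17,BL20
S17,BL23
S17,HT3
S18,PC6
S18,ST36
S18,BL15
S18,HT6
S19,PC6
S19,ST36
S19,BL15
S19,Xiongtong
S20,PC6
S20,ST36
S20,BL15
S21,PC6
S21,ST36
S21,HT7
S22,PC6
S22,ST36
S22,HT7
S23,PC6
S23,ST36
S23,HT7
S24,PC6
S24,ST36
S24,LI11
S24,ST40
S24,RN4
S24,SP6
S24,HT4
S25,PC6
S25,ST36
S25,LI11
S25,ST40
S25,RN17
S25,RN6
S25,PC2
S26,PC6
S26,LI11
S26,LR3
S26,RN17
S26,BL23
S26,RN14
S26,PC3
S27,ST36
S27,LR3
S27,BL17
S27,KI3
S27,PC7
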