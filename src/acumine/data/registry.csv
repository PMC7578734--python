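code,meridian,display_name
PC6,PC,Neiguan
PC4,PC,Ximen
PC2,PC,Tianquan
PC3,PC,Quze
PC7,PC,Daling
LU9,LU,Taiyuan
LU6,LU,Kongzui
LU1,LU,Zhongfu
LU7,LU,Lieque
HT7,HT,Shenmen
HT5,HT,Tongli
HT1,HT,Jiquan
HT4,HT,Lingdao
HT3,HT,Shaohai
HT6,HT,Yinxi
ST36,ST,Zusanli
ST40,ST,Fenglong
BL15,BL,Xinshu
BL14,BL,Jueyinshu
BL17,BL,Geshu
BL20,BL,Pishu
BL23,BL,Shenshu
BL13,BL,Feishu
RN17,RN,Danzhong
RN4,RN,Guanyuan
RN6,RN,Qihai
RN14,RN,Juque
RN12,RN,Zhongwan
LI11,LI,Quchi
LI4,LI,Hegu
LR3,LR,Taichong
SP6,SP,Sanyinjiao
SP10,SP,Xuehai
SP8,SP,Diji
SP9,SP,Yinlingquan
KI3,KI,Taixi
Xiongtong,,Chest pain point (experience point)
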