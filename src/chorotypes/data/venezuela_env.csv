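unit,MA,MDP,TR,ME
A2,50,8,8,500
B1,61,20,9,1000
B2,150,5,10,1050
B3,51,25,8,1100
B4,202,25,9,1200
B5,642,30,10,1250
C1,406,5,8,750
C2,348,25,9,1100
D1,1561,5,9,1300
D2,1791,25,8,900
D3,529,8,8,800
D4,1066,5,10,900
D5,598,10,8,800
D6,198,5,8,400
D7,855,65,11,1300
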