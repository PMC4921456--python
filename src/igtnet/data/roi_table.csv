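name,network,x,y,z,radius
R_VLPFC,FPN,40,48,-5,10
L_VLPFC,FPN,-40,48,-5,10
R_DLPFC,FPN,43,22,34,10
L_DLPFC,FPN,-43,22,34,10
R_SPC,FPN,37,-61,48,10
L_SPC,FPN,-32,-61,48,10
dACC,FPN,-2,35,43,10
R_IPC,DMN,55,-57,25,10
L_IPC,DMN,-55,-57,25,10
vmPFC,DMN,0,57,-10,10
Precuneus_PCC,DMN,0,-51,31,10
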