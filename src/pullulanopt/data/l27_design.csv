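run,sucrose,K2HPO4,NaCl,MgSO4,yeast_extract,pH,incubation_time
L1,40,4,0.5,0.1,1,5.5,48
L2,40,4,0.5,0.1,2,6.5,72
L3,40,4,0.5,0.1,3,7.5,96
L4,40,5,1.0,0.2,1,5.5,48
L5,40,5,1.0,0.2,2,6.5,72
L6,40,5,1.0,0.2,3,7.5,96
L7,40,6,1.5,0.3,1,5.5,48
L8,40,6,1.5,0.3,2,6.5,72
L9,40,6,1.5,0.3,3,7.5,96
L10,50,4,1.0,0.3,1,6.5,96
L11,50,4,1.0,0.3,2,7.5,48
L12,50,4,1.0,0.3,3,5.5,72
L13,50,5,1.5,0.1,1,6.5,96
L14,50,5,1.5,0.1,2,7.5,48
L15,50,5,1.5,0.1,3,5.5,72
L16,50,6,0.5,0.2,1,6.5,96
L17,50,6,0.5,0.2,2,7.5,48
L18,50,6,0.5,0.2,3,5.5,72
L19,60,4,1.5,0.2,1,7.5,72
L20,60,4,1.5,0.2,2,5.5,96
L21,60,4,1.5,0.2,3,6.5,48
L22,60,5,0.5,0.3,1,7.5,72
L23,60,5,0.5,0.3,2,5.5,96
L24,60,5,0.5,0.3,3,6.5,48
L25,60,6,1.0,0.1,1,7.5,72
L26,60,6,1.0,0.1,2,5.5,96
L27,60,6,1.0,0.1,3,6.5,48
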