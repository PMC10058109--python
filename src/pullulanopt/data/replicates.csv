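run,block,partition,dt_fitted,dt_residual,terminal_node
L1,1,Test,2.95,1.04,1
L2,1,Test,2.95,0.16,1
L3,1,Training,2.95,-0.62,1
L4,1,Test,5.24,0.19,4
L5,1,Training,5.24,-0.25,4
L6,1,Test,4.65,-0.19,5
L7,1,Training,6.98,0.35,7
L8,1,Test,6.98,-0.57,7
L9,1,Training,5.76,0.15,9
L10,1,Training,5.76,-0.26,9
L11,1,Training,6.01,-0.26,8
L12,1,Test,6.01,0.13,8
L13,1,Test,4.76,-0.09,2
L14,1,Training,5.13,-0.21,3
L15,1,Training,5.13,0.12,3
L16,1,Training,4.65,0.23,5
L17,1,Training,5.24,0.04,4
L18,1,Training,5.24,0.19,4
L19,1,Training,5.80,-0.31,6
L20,1,Test,5.80,-0.32,6
L21,1,Training,5.80,0.32,6
L22,1,Test,6.01,-0.63,8
L23,1,Test,5.76,-0.06,9
L24,1,Test,6.01,0.29,8
L25,1,Training,4.76,-0.06,2
L26,1,Test,5.13,0.07,3
L27,1,Training,5.13,0.31,3
L1,2,Training,2.95,0.95,1
L2,2,Training,2.95,0.27,1
L3,2,Training,2.95,-0.64,1
L4,2,Test,5.24,0.14,4
L5,2,Test,5.24,-0.35,4
L6,2,Training,4.65,-0.18,5
L7,2,Test,6.98,0.19,7
L8,2,Training,6.98,-0.33,7
L9,2,Training,5.76,0.02,9
L10,2,Training,5.76,-0.28,9
L11,2,Test,6.01,-0.12,8
L12,2,Training,6.01,0.19,8
L13,2,Training,4.76,-0.01,2
L14,2,Training,5.13,-0.30,3
L15,2,Test,5.13,0.11,3
L16,2,Training,4.65,0.18,5
L17,2,Training,5.24,-0.05,4
L18,2,Test,5.24,0.26,4
L19,2,Training,5.80,-0.30,6
L20,2,Training,5.80,-0.27,6
L21,2,Training,5.80,0.30,6
L22,2,Training,6.01,-0.44,8
L23,2,Training,5.76,0.17,9
L24,2,Training,6.01,0.22,8
L25,2,Training,4.76,0.05,2
L26,2,Training,5.13,0.19,3
L27,2,Test,5.13,0.51,3
L1,3,Test,2.95,0.60,1
L2,3,Training,2.95,0.06,1
L3,3,Test,2.95,-0.64,1
L4,3,Test,5.24,0.06,4
L5,3,Training,5.24,-0.30,4
L6,3,Training,4.65,-0.35,5
L7,3,Training,6.98,0.21,7
L8,3,Training,6.98,-0.23,7
L9,3,Training,5.76,0.19,9
L10,3,Test,5.76,-0.46,9
L11,3,Training,6.01,-0.12,8
L12,3,Test,6.01,0.23,8
L13,3,Training,4.76,0.03,2
L14,3,Training,5.13,-0.16,3
L15,3,Training,5.13,0.04,3
L16,3,Training,4.65,0.12,5
L17,3,Training,5.24,0.02,4
L18,3,Training,5.24,0.36,4
L19,3,Training,5.80,-0.22,6
L20,3,Test,5.80,-0.20,6
L21,3,Training,5.80,0.51,6
L22,3,Test,6.01,-0.36,8
L23,3,Training,5.76,0.02,9
L24,3,Training,6.01,0.41,8
L25,3,Test,4.76,-0.10,2
L26,3,Training,5.13,-0.01,3
L27,3,Test,5.13,0.22,3
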