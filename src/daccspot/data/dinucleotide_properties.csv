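property,AA/TT,AC/GT,AG/CT,AT,CA/TG,CC/GG,CG,GA/TC,GC,TA
F-roll,0.04,0.06,0.04,0.05,0.04,0.04,0.04,0.05,0.05,0.03
F-tilt,0.08,0.07,0.06,0.10,0.06,0.06,0.06,0.07,0.07,0.07
F-twist,0.07,0.06,0.05,0.07,0.05,0.06,0.05,0.06,0.06,0.05
F-slide,6.69,6.80,3.47,9.61,2.00,2.99,2.71,4.27,4.21,1.85
F-shift,6.24,2.91,2.80,4.66,2.88,2.67,3.02,3.58,2.66,4.11
F-rise,21.34,21.98,17.48,24.79,14.51,14.25,14.66,18.41,17.31,14.24
roll,1.05,2.01,3.60,0.61,5.60,4.68,6.02,2.44,1.70,3.50
tilt,-1.26,0.33,-1.66,0.00,0.14,-0.77,0.00,1.44,0.00,0.00
twist,35.02,31.53,32.29,30.72,35.43,33.54,33.67,35.67,34.07,36.94
slide,-0.18,-0.59,-0.22,-0.68,0.48,-0.17,0.44,-0.05,-0.19,0.04
shift,0.01,-0.02,-0.02,0.00,0.01,0.03,0.00,-0.01,0.00,0.00
rise,3.25,3.24,3.32,3.21,3.37,3.36,3.29,3.30,3.27,3.39
energy,-1.00,-1.44,-1.28,-0.88,-1.45,-1.84,-2.17,-1.30,-2.24,-0.58
enthalpy,-7.60,-8.40,-7.80,-7.20,-8.50,-8.00,-10.60,-8.20,-9.80,-7.20
entropy,-21.30,-22.40,-21.00,-20.40,-22.70,-19.90,-27.20,-22.20,-24.40,-21.30
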