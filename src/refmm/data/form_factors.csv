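# 4-Gaussian + constant X-ray scattering factors, f(s) = sum a_i exp(-b_i s^2) + c
# with s = sin(theta)/lambda (A^-1).  Standard International Tables (1992)
# neutral-atom coefficients for the supported elements.
element,a1,a2,a3,a4,b1,b2,b3,b4,c
H,0.493002,0.322912,0.140191,0.040810,10.5109,26.1257,3.14236,57.7997,0.003038
C,2.31000,1.02000,1.58860,0.865000,20.8439,10.2075,0.568700,51.6512,0.215600
N,12.2126,3.13220,2.01250,1.16630,0.005700,9.89330,28.9975,0.582600,-11.5290
O,3.04850,2.28680,1.54630,0.867000,13.2771,5.70110,0.323900,32.9089,0.250800
S,6.90530,5.20340,1.43790,1.58630,1.46790,22.2151,0.253600,56.1720,0.866900
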