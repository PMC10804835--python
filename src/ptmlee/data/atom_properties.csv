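# ptmlee atomic property table, version 1.0
# Zv: valence-electron count
# Vvdw: van der Waals volume (A^3) from Bondi radii, V = 4/3*pi*r^3 (B from Batsanov)
# chi: Sanderson electronegativity (dimensionless)
# alpha: static dipole polarizability (A^3), CRC values
# EA: electron affinity (eV); N listed as ~0 (anion unbound)
element,Zv,Vvdw,chi,alpha,EA
H,1,7.24,2.592,0.667,0.754
B,3,29.65,2.275,3.030,0.280
C,4,20.58,2.746,1.760,1.262
N,5,15.60,3.194,1.100,0.000
O,6,14.71,3.654,0.802,1.461
F,7,13.31,4.000,0.557,3.401
Si,4,38.79,2.138,5.380,1.390
P,5,24.43,2.515,3.630,0.746
S,6,24.43,2.957,2.900,2.077
Cl,7,22.45,3.475,2.180,3.613
Br,7,26.52,3.219,3.050,3.364
I,7,32.52,2.778,5.350,3.059
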