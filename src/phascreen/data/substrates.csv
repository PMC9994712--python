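name,acetyl_coa_equiv,conc_g_per_L,molar_mass,n_atoms,supplied_form
Sucrose,4,8.0,342.30,0,free
L-Arabinose,2,7.0,150.13,0,free
D-Galactose,2,8.5,180.16,0,free
D-Mannitol,2,8.5,182.17,0,free
D-Fructose,2,8.5,180.16,0,free
a-D-Glucose,2,8.5,180.16,0,free
D-L-Malic acid,1,12.5,134.09,0,free acid
Na-gluconate,2,9.1,218.14,0,sodium salt
Xylose,2,6.9,150.13,0,free
L-Lactic acid,1,8.4,90.08,0,free acid
Na-acetate,1,5.6,82.03,0,sodium salt (anhydrous)
Mannose,2,8.4,180.16,0,free
N-acetylglucosamine,2,10.3,221.21,1,free
Ethanol,1,4.5,46.07,0,free
Glycerol,1,8.6,92.09,0,free
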