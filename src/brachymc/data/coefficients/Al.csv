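# generated by scripts/make_coefficient_tables.py
# element Al (Z=13); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,2.737190e+01,2.718956e+01
1.085847e-02,2.069106e+01,2.050958e+01
1.179065e-02,1.567509e+01,1.549453e+01
1.280284e-02,1.190345e+01,1.172388e+01
1.390193e-02,9.063183e+00,8.884675e+00
1.509538e-02,6.921044e+00,6.743676e+00
1.639128e-02,5.302968e+00,5.126819e+00
1.779843e-02,4.078854e+00,3.904010e+00
1.932638e-02,3.151328e+00,2.977877e+00
1.999998e-02,2.834844e+00,2.662000e+00
2.000002e-02,2.834827e+00,2.661983e+00
2.098549e-02,2.447401e+00,2.275437e+00
2.278704e-02,1.912288e+00,1.741907e+00
2.474325e-02,1.504805e+00,1.336109e+00
2.686740e-02,1.193952e+00,1.027046e+00
2.917389e-02,9.563585e-01,7.913498e-01
3.167840e-02,7.743803e-01,6.113801e-01
3.439791e-02,6.346790e-01,4.738010e-01
3.735088e-02,5.271559e-01,3.685157e-01
4.055735e-02,4.441541e-01,2.878688e-01
4.403910e-02,3.798605e-01,2.260477e-01
4.781974e-02,3.298549e-01,1.786325e-01
5.192494e-02,2.907722e-01,1.422569e-01
5.638256e-02,2.600469e-01,1.143536e-01
6.122286e-02,2.357205e-01,9.296127e-02
6.647868e-02,2.162963e-01,7.657936e-02
7.218571e-02,2.006290e-01,6.405771e-02
7.611092e-02,1.921234e-01,5.762630e-02
7.611108e-02,1.921231e-01,5.762608e-02
7.838266e-02,1.878416e-01,5.451331e-02
8.511161e-02,1.772618e-01,4.726698e-02
9.241822e-02,1.683743e-01,4.179530e-02
1.003521e-01,1.607836e-01,3.769413e-02
1.089671e-01,1.541869e-01,3.465069e-02
1.183216e-01,1.483518e-01,3.242246e-02
1.284792e-01,1.431009e-01,3.082090e-02
1.395088e-01,1.382986e-01,2.969919e-02
1.514853e-01,1.338418e-01,2.894267e-02
1.644899e-01,1.296524e-01,2.846168e-02
1.786109e-01,1.256717e-01,2.818593e-02
1.939442e-01,1.218557e-01,2.806029e-02
2.105938e-01,1.181717e-01,2.804143e-02
2.286728e-01,1.145959e-01,2.809531e-02
2.483037e-01,1.111109e-01,2.819516e-02
2.696199e-01,1.077045e-01,2.831998e-02
2.927661e-01,1.043679e-01,2.845328e-02
3.178993e-01,1.010953e-01,2.858219e-02
3.451902e-01,9.788258e-02,2.869664e-02
3.748239e-01,9.472727e-02,2.878883e-02
4.070015e-01,9.162771e-02,2.885273e-02
4.419415e-01,8.858295e-02,2.888373e-02
4.798811e-01,8.559243e-02,2.887836e-02
5.210776e-01,8.265586e-02,2.883406e-02
5.658108e-01,7.977315e-02,2.874900e-02
6.143842e-01,7.694428e-02,2.862200e-02
6.671275e-01,7.416932e-02,2.845240e-02
7.243986e-01,7.144840e-02,2.824000e-02
7.865864e-01,6.878170e-02,2.798500e-02
8.541128e-01,6.616945e-02,2.768801e-02
9.274362e-01,6.361196e-02,2.734997e-02
1.007054e+00,6.110959e-02,2.697216e-02
1.093507e+00,5.866278e-02,2.655615e-02
1.187382e+00,5.627200e-02,2.610379e-02
1.289316e+00,5.393780e-02,2.561721e-02
1.400000e+00,5.166075e-02,2.509875e-02
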