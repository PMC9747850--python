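# generated by scripts/make_coefficient_tables.py
# element Ar (Z=18); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,7.347628e+01,7.330575e+01
1.085847e-02,5.550415e+01,5.533442e+01
1.179065e-02,4.200131e+01,4.183245e+01
1.280284e-02,3.184123e+01,3.167329e+01
1.390193e-02,2.418495e+01,2.401801e+01
1.509538e-02,1.840684e+01,1.824096e+01
1.639128e-02,1.403960e+01,1.387487e+01
1.779843e-02,1.073378e+01,1.057026e+01
1.932638e-02,8.227616e+00,8.065404e+00
1.999998e-02,7.372197e+00,7.210552e+00
2.000002e-02,7.372150e+00,7.210505e+00
2.098549e-02,6.324779e+00,6.163957e+00
2.278704e-02,4.877800e+00,4.718459e+00
2.474325e-02,3.775750e+00,3.617985e+00
2.686740e-02,2.935068e+00,2.778976e+00
2.917389e-02,2.292720e+00,2.138402e+00
3.167840e-02,1.801084e+00,1.648645e+00
3.439791e-02,1.424136e+00,1.273682e+00
3.735088e-02,1.134583e+00,9.862216e-01
4.055735e-02,9.117188e-01,7.655595e-01
4.403910e-02,7.398110e-01,5.959641e-01
4.781974e-02,6.068901e-01,4.654657e-01
5.192494e-02,5.038367e-01,3.649440e-01
5.638256e-02,4.236929e-01,2.874393e-01
6.122286e-02,3.611426e-01,2.276330e-01
6.647868e-02,3.121189e-01,1.814546e-01
7.218571e-02,2.735066e-01,1.457840e-01
7.611092e-02,2.530445e-01,1.272618e-01
7.611108e-02,2.530438e-01,1.272611e-01
7.838266e-02,2.429158e-01,1.182262e-01
8.511161e-02,2.185118e-01,9.693961e-02
9.241822e-02,1.988838e-01,8.050615e-02
1.003521e-01,1.829463e-01,6.783198e-02
1.089671e-01,1.698632e-01,5.807197e-02
1.183216e-01,1.589902e-01,5.057211e-02
1.284792e-01,1.498306e-01,4.482537e-02
1.395088e-01,1.420011e-01,4.043804e-02
1.514853e-01,1.352064e-01,3.710387e-02
1.644899e-01,1.292187e-01,3.458425e-02
1.786109e-01,1.238625e-01,3.269300e-02
1.939442e-01,1.190028e-01,3.128464e-02
2.105938e-01,1.145359e-01,3.024532e-02
2.286728e-01,1.103819e-01,2.948589e-02
2.483037e-01,1.064799e-01,2.893644e-02
2.696199e-01,1.027832e-01,2.854214e-02
2.927661e-01,9.925594e-02,2.825997e-02
3.178993e-01,9.587096e-02,2.805615e-02
3.451902e-01,9.260743e-02,2.790418e-02
3.748239e-01,8.944945e-02,2.778329e-02
4.070015e-01,8.638487e-02,2.767719e-02
4.419415e-01,8.340437e-02,2.757318e-02
4.798811e-01,8.050078e-02,2.746133e-02
5.210776e-01,7.766856e-02,2.733397e-02
5.658108e-01,7.490341e-02,2.718522e-02
6.143842e-01,7.220200e-02,2.701061e-02
6.671275e-01,6.956173e-02,2.680690e-02
7.243986e-01,6.698061e-02,2.657176e-02
7.865864e-01,6.445712e-02,2.630372e-02
8.541128e-01,6.199014e-02,2.600198e-02
9.274362e-01,5.957886e-02,2.566636e-02
1.007054e+00,5.722276e-02,2.529716e-02
1.093507e+00,5.492155e-02,2.489517e-02
1.187382e+00,5.267513e-02,2.446158e-02
1.289316e+00,5.048354e-02,2.399790e-02
1.400000e+00,4.834697e-02,2.350597e-02
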