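# generated by scripts/make_coefficient_tables.py
# element Ti (Z=22); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,1.438259e+02,1.436519e+02
1.085847e-02,1.086560e+02,1.084829e+02
1.179065e-02,8.222059e+01,8.204834e+01
1.280284e-02,6.232086e+01,6.214956e+01
1.390193e-02,4.731868e+01,4.714840e+01
1.509538e-02,3.599187e+01,3.582267e+01
1.639128e-02,2.742723e+01,2.725919e+01
1.779843e-02,2.094150e+01,2.077471e+01
1.932638e-02,1.602269e+01,1.585723e+01
1.999998e-02,1.434332e+01,1.417844e+01
2.000002e-02,1.434322e+01,1.417834e+01
2.098549e-02,1.228664e+01,1.212260e+01
2.278704e-02,9.444648e+00,9.282116e+00
2.474325e-02,7.279466e+00,7.118541e+00
2.686740e-02,5.627375e+00,5.468158e+00
2.917389e-02,4.364819e+00,4.207412e+00
3.167840e-02,3.398420e+00,3.242929e+00
3.439791e-02,2.657504e+00,2.504037e+00
3.735088e-02,2.088507e+00,1.937175e+00
4.055735e-02,1.650774e+00,1.501688e+00
4.403910e-02,1.313403e+00,1.166677e+00
4.781974e-02,1.052875e+00,9.086194e-01
5.192494e-02,8.512608e-01,7.095873e-01
5.638256e-02,6.948756e-01,5.558942e-01
6.122286e-02,5.732596e-01,4.370770e-01
6.647868e-02,4.784061e-01,3.451257e-01
7.218571e-02,4.041786e-01,2.738989e-01
7.611092e-02,3.651107e-01,2.368096e-01
7.611108e-02,3.651093e-01,2.368083e-01
7.838266e-02,3.458671e-01,2.186810e-01
8.511161e-02,2.998521e-01,1.758459e-01
9.241822e-02,2.633487e-01,1.426011e-01
1.003521e-01,2.342114e-01,1.167924e-01
1.089671e-01,2.107855e-01,9.675615e-02
1.183216e-01,1.917936e-01,8.120489e-02
1.284792e-01,1.762485e-01,6.914108e-02
1.395088e-01,1.633869e-01,5.979052e-02
1.514853e-01,1.526180e-01,5.255143e-02
1.644899e-01,1.434844e-01,4.695531e-02
1.786109e-01,1.356317e-01,4.263691e-02
1.939442e-01,1.287854e-01,3.931105e-02
2.105938e-01,1.227329e-01,3.675481e-02
2.286728e-01,1.173093e-01,3.479366e-02
2.483037e-01,1.123868e-01,3.329086e-02
2.696199e-01,1.078665e-01,3.213913e-02
2.927661e-01,1.036716e-01,3.125426e-02
3.178993e-01,9.974260e-02,3.057008e-02
3.451902e-01,9.603324e-02,3.003458e-02
3.748239e-01,9.250761e-02,2.960685e-02
4.070015e-01,8.913777e-02,2.925472e-02
4.419415e-01,8.590188e-02,2.895290e-02
4.798811e-01,8.278288e-02,2.868154e-02
5.210776e-01,7.976739e-02,2.842506e-02
5.658108e-01,7.684488e-02,2.817133e-02
6.143842e-01,7.400705e-02,2.791090e-02
6.671275e-01,7.124737e-02,2.763656e-02
7.243986e-01,6.856071e-02,2.734285e-02
7.865864e-01,6.594303e-02,2.702577e-02
8.541128e-01,6.339121e-02,2.668255e-02
9.274362e-01,6.090283e-02,2.631137e-02
1.007054e+00,5.847610e-02,2.591132e-02
1.093507e+00,5.610968e-02,2.548215e-02
1.187382e+00,5.380266e-02,2.502425e-02
1.289316e+00,5.155442e-02,2.453851e-02
1.400000e+00,4.936460e-02,2.402627e-02
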