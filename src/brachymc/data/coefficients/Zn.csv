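# generated by scripts/make_coefficient_tables.py
# element Zn (Z=30); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,3.936187e+02,3.934451e+02
1.085847e-02,2.975000e+02,2.973271e+02
1.179065e-02,2.252032e+02,2.250312e+02
1.280284e-02,1.707435e+02,1.705725e+02
1.390193e-02,1.296592e+02,1.294892e+02
1.509538e-02,9.861921e+01,9.845029e+01
1.639128e-02,7.513303e+01,7.496528e+01
1.779843e-02,5.733595e+01,5.716943e+01
1.932638e-02,4.382980e+01,4.366461e+01
1.999998e-02,3.921640e+01,3.905179e+01
2.000002e-02,3.921614e+01,3.905153e+01
2.098549e-02,3.356475e+01,3.340098e+01
2.278704e-02,2.575138e+01,2.558911e+01
2.474325e-02,1.979522e+01,1.963456e+01
2.686740e-02,1.524801e+01,1.508905e+01
2.917389e-02,1.177120e+01,1.161405e+01
3.167840e-02,9.108797e+00,8.953560e+00
3.439791e-02,7.066899e+00,6.913683e+00
3.735088e-02,5.498461e+00,5.347376e+00
4.055735e-02,4.291802e+00,4.142960e+00
4.403910e-02,3.361979e+00,3.215492e+00
4.781974e-02,2.644295e+00,2.500275e+00
5.192494e-02,2.089403e+00,1.947961e+00
5.638256e-02,1.659611e+00,1.520857e+00
6.122286e-02,1.326090e+00,1.190130e+00
6.647868e-02,1.066756e+00,9.336930e-01
7.218571e-02,8.646699e-01,7.346031e-01
7.611092e-02,7.587958e-01,6.307043e-01
7.611108e-02,7.587921e-01,6.307007e-01
7.838266e-02,7.068221e-01,5.798439e-01
8.511161e-02,5.832052e-01,4.594016e-01
9.241822e-02,4.861115e-01,3.655611e-01
1.003521e-01,4.095969e-01,2.923698e-01
1.089671e-01,3.490709e-01,2.352279e-01
1.183216e-01,3.009842e-01,1.905762e-01
1.284792e-01,2.625889e-01,1.556565e-01
1.395088e-01,2.317553e-01,1.283281e-01
1.514853e-01,2.068304e-01,1.069273e-01
1.644899e-01,1.865304e-01,9.015909e-02
1.786109e-01,1.698570e-01,7.701415e-02
1.939442e-01,1.560328e-01,6.670458e-02
2.105938e-01,1.444522e-01,5.861456e-02
2.286728e-01,1.346429e-01,5.226211e-02
2.483037e-01,1.262362e-01,4.726948e-02
2.696199e-01,1.189439e-01,4.334027e-02
2.927661e-01,1.125407e-01,4.024163e-02
3.178993e-01,1.068499e-01,3.779038e-02
3.451902e-01,1.017332e-01,3.584234e-02
3.748239e-01,9.708181e-02,3.428381e-02
4.070015e-01,9.281034e-02,3.302513e-02
4.419415e-01,8.885143e-02,3.199549e-02
4.798811e-01,8.515192e-02,3.113897e-02
5.210776e-01,8.166981e-02,3.041137e-02
5.658108e-01,7.837181e-02,2.977778e-02
6.143842e-01,7.523153e-02,2.921069e-02
6.671275e-01,7.222800e-02,2.868843e-02
7.243986e-01,6.934456e-02,2.819404e-02
7.865864e-01,6.656799e-02,2.771432e-02
8.541128e-01,6.388780e-02,2.723911e-02
9.274362e-01,6.129566e-02,2.676072e-02
1.007054e+00,5.878506e-02,2.627348e-02
1.093507e+00,5.635084e-02,2.577335e-02
1.187382e+00,5.398903e-02,2.525764e-02
1.289316e+00,5.169656e-02,2.472479e-02
1.400000e+00,4.947106e-02,2.417413e-02
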