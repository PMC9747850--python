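# generated by scripts/make_coefficient_tables.py
# element Ir (Z=77); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,1.341584e+03,1.341432e+03
1.085847e-02,1.016026e+03,1.015875e+03
1.179065e-02,7.706438e+02,7.704937e+02
1.280284e-02,5.854179e+02,5.852686e+02
1.390193e-02,4.453932e+02,4.452447e+02
1.509538e-02,3.393819e+02,3.392344e+02
1.639128e-02,2.590028e+02,2.588563e+02
1.779843e-02,1.979678e+02,1.978225e+02
1.932638e-02,1.515529e+02,1.514087e+02
1.999998e-02,1.356748e+02,1.355311e+02
2.000002e-02,1.356739e+02,1.355302e+02
2.098549e-02,1.162035e+02,1.160606e+02
2.278704e-02,8.924173e+01,8.910007e+01
2.474325e-02,6.864674e+01,6.850648e+01
2.686740e-02,5.289172e+01,5.275295e+01
2.917389e-02,4.082131e+01,4.068412e+01
3.167840e-02,3.156001e+01,3.142449e+01
3.439791e-02,2.444346e+01,2.430970e+01
3.735088e-02,1.896678e+01,1.883488e+01
4.055735e-02,1.474577e+01,1.461583e+01
4.403910e-02,1.148761e+01,1.135972e+01
4.781974e-02,8.968839e+00,8.843107e+00
5.192494e-02,7.018681e+00,6.895199e+00
5.638256e-02,5.506425e+00,5.385290e+00
6.122286e-02,4.331893e+00,4.213197e+00
6.647868e-02,3.418198e+00,3.302032e+00
7.218571e-02,2.706244e+00,2.592693e+00
7.611092e-02,2.333445e+00,2.221619e+00
7.611108e-02,1.226669e+01,1.215487e+01
7.838266e-02,1.126413e+01,1.115328e+01
8.511161e-02,8.883882e+00,8.775799e+00
9.241822e-02,7.021729e+00,6.916486e+00
1.003521e-01,5.562629e+00,5.460288e+00
1.089671e-01,4.417536e+00,4.318149e+00
1.183216e-01,3.517426e+00,3.421038e+00
1.284792e-01,2.808724e+00,2.715371e+00
1.395088e-01,2.249786e+00,2.159492e+00
1.514853e-01,1.808196e+00,1.720979e+00
1.644899e-01,1.458689e+00,1.374555e+00
1.786109e-01,1.181542e+00,1.100489e+00
1.939442e-01,9.613417e-01,8.833567e-01
2.105938e-01,7.860222e-01,7.110845e-01
2.286728e-01,6.461271e-01,5.742073e-01
2.483037e-01,5.342341e-01,4.652948e-01
2.696199e-01,4.445098e-01,3.785066e-01
2.927661e-01,3.723631e-01,3.092448e-01
3.178993e-01,3.141754e-01,2.538853e-01
3.451902e-01,2.670910e-01,2.095672e-01
3.748239e-01,2.288530e-01,1.740293e-01
4.070015e-01,1.976751e-01,1.454816e-01
4.419415e-01,1.721417e-01,1.225055e-01
4.798811e-01,1.511291e-01,1.039749e-01
5.210776e-01,1.337445e-01,8.899503e-02
5.658108e-01,1.192771e-01,7.685374e-02
6.143842e-01,1.071606e-01,6.698366e-02
6.671275e-01,9.694290e-02,5.893213e-02
7.243986e-01,8.826272e-02,5.233762e-02
7.865864e-01,8.083101e-02,4.691110e-02
8.541128e-01,7.441615e-02,4.242123e-02
9.274362e-01,6.883234e-02,3.868276e-02
1.007054e+00,6.393036e-02,3.554721e-02
1.093507e+00,5.959023e-02,3.289556e-02
1.187382e+00,5.571536e-02,3.063237e-02
1.289316e+00,5.222794e-02,2.868114e-02
1.400000e+00,4.906520e-02,2.698056e-02
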