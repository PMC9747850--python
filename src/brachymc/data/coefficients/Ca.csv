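# generated by scripts/make_coefficient_tables.py
# element Ca (Z=20); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,1.145733e+02,1.143845e+02
1.085847e-02,8.655044e+01,8.636246e+01
1.179065e-02,6.549144e+01,6.530442e+01
1.280284e-02,4.964219e+01,4.945620e+01
1.390193e-02,3.769608e+01,3.751119e+01
1.509538e-02,2.867846e+01,2.849475e+01
1.639128e-02,2.186126e+01,2.167881e+01
1.779843e-02,1.669982e+01,1.651873e+01
1.932638e-02,1.278611e+01,1.260646e+01
1.999998e-02,1.145008e+01,1.127105e+01
2.000002e-02,1.145000e+01,1.127098e+01
2.098549e-02,9.814017e+00,9.635905e+00
2.278704e-02,7.553548e+00,7.377077e+00
2.474325e-02,5.831671e+00,5.656945e+00
2.686740e-02,4.518010e+00,4.345137e+00
2.917389e-02,3.514195e+00,3.343287e+00
3.167840e-02,2.745894e+00,2.577067e+00
3.439791e-02,2.156863e+00,1.990234e+00
3.735088e-02,1.704481e+00,1.540170e+00
4.055735e-02,1.356406e+00,1.194534e+00
4.403910e-02,1.088059e+00,9.287476e-01
4.781974e-02,8.807365e-01,7.241079e-01
5.192494e-02,7.201846e-01,5.663599e-01
5.638256e-02,5.955257e-01,4.446239e-01
6.122286e-02,4.984469e-01,3.505841e-01
6.647868e-02,4.225868e-01,2.778751e-01
7.218571e-02,3.630710e-01,2.216174e-01
7.611092e-02,3.316612e-01,1.923559e-01
7.611108e-02,3.316601e-01,1.923549e-01
7.838266e-02,3.161593e-01,1.780646e-01
8.511161e-02,2.789784e-01,1.443363e-01
9.241822e-02,2.493183e-01,1.182142e-01
1.003521e-01,2.254772e-01,9.798733e-02
1.089671e-01,2.061436e-01,8.233406e-02
1.183216e-01,1.903055e-01,7.023172e-02
1.284792e-01,1.771817e-01,6.088774e-02
1.395088e-01,1.661687e-01,5.368690e-02
1.514853e-01,1.568001e-01,4.815089e-02
1.644899e-01,1.487155e-01,4.390722e-02
1.786109e-01,1.416362e-01,4.066540e-02
1.939442e-01,1.353471e-01,3.819857e-02
2.105938e-01,1.296817e-01,3.632931e-02
2.286728e-01,1.245116e-01,3.491873e-02
2.483037e-01,1.197379e-01,3.385795e-02
2.696199e-01,1.152840e-01,3.306158e-02
2.927661e-01,1.110911e-01,3.246260e-02
3.178993e-01,1.071138e-01,3.200837e-02
3.451902e-01,1.033168e-01,3.165754e-02
3.748239e-01,9.967335e-02,3.137764e-02
4.070015e-01,9.616234e-02,3.114317e-02
4.419415e-01,9.276756e-02,3.093412e-02
4.798811e-01,8.947641e-02,3.073484e-02
5.210776e-01,8.627903e-02,3.053312e-02
5.658108e-01,8.316771e-02,3.031947e-02
6.143842e-01,8.013641e-02,3.008664e-02
6.671275e-01,7.718041e-02,2.982913e-02
7.243986e-01,7.429599e-02,2.954290e-02
7.865864e-01,7.148028e-02,2.922513e-02
8.541128e-01,6.873110e-02,2.887397e-02
9.274362e-01,6.604679e-02,2.848845e-02
1.007054e+00,6.342615e-02,2.806832e-02
1.093507e+00,6.086838e-02,2.761396e-02
1.187382e+00,5.837297e-02,2.712626e-02
1.289316e+00,5.593966e-02,2.660662e-02
1.400000e+00,5.356838e-02,2.605680e-02
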