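# generated by scripts/make_coefficient_tables.py
# element N (Z=7); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,3.955002e+00,3.765865e+00
1.085847e-02,3.025968e+00,2.837722e+00
1.179065e-02,2.329232e+00,2.141943e+00
1.280284e-02,1.805870e+00,1.619609e+00
1.390193e-02,1.412089e+00,1.226931e+00
1.509538e-02,1.115294e+00,9.313185e-01
1.639128e-02,8.911909e-01,7.084804e-01
1.779843e-02,7.216438e-01,5.402865e-01
1.932638e-02,5.930967e-01,4.131848e-01
1.999998e-02,5.491955e-01,3.699131e-01
2.000002e-02,5.491931e-01,3.699107e-01
2.098549e-02,4.954011e-01,3.170313e-01
2.278704e-02,4.209487e-01,2.442216e-01
2.474325e-02,3.640270e-01,1.890474e-01
2.686740e-02,3.203407e-01,1.472172e-01
2.917389e-02,2.866555e-01,1.155001e-01
3.167840e-02,2.605321e-01,9.146014e-02
3.439791e-02,2.401286e-01,7.325777e-02
3.735088e-02,2.240515e-01,5.950186e-02
4.055735e-02,2.112457e-01,4.913862e-02
4.403910e-02,2.009108e-01,4.136848e-02
4.781974e-02,1.924392e-01,3.558364e-02
5.192494e-02,1.853688e-01,3.132116e-02
5.638256e-02,1.793482e-01,2.822769e-02
6.122286e-02,1.741099e-01,2.603281e-02
6.647868e-02,1.694505e-01,2.452901e-02
7.218571e-02,1.652152e-01,2.355651e-02
7.611092e-02,1.626604e-01,2.315320e-02
7.611108e-02,1.626603e-01,2.315318e-02
7.838266e-02,1.612866e-01,2.299182e-02
8.511161e-02,1.575763e-01,2.273907e-02
9.241822e-02,1.540176e-01,2.272347e-02
1.003521e-01,1.505610e-01,2.288635e-02
1.089671e-01,1.471704e-01,2.318139e-02
1.183216e-01,1.438197e-01,2.357183e-02
1.284792e-01,1.404908e-01,2.402827e-02
1.395088e-01,1.371719e-01,2.452709e-02
1.514853e-01,1.338559e-01,2.504920e-02
1.644899e-01,1.305393e-01,2.557914e-02
1.786109e-01,1.272215e-01,2.610432e-02
1.939442e-01,1.239038e-01,2.661453e-02
2.105938e-01,1.205891e-01,2.710149e-02
2.286728e-01,1.172813e-01,2.755850e-02
2.483037e-01,1.139846e-01,2.798021e-02
2.696199e-01,1.107040e-01,2.836236e-02
2.927661e-01,1.074441e-01,2.870163e-02
3.178993e-01,1.042097e-01,2.899545e-02
3.451902e-01,1.010051e-01,2.924189e-02
3.748239e-01,9.783425e-02,2.943956e-02
4.070015e-01,9.470089e-02,2.958750e-02
4.419415e-01,9.160813e-02,2.968508e-02
4.798811e-01,8.855871e-02,2.973201e-02
5.210776e-01,8.555495e-02,2.972824e-02
5.658108e-01,8.259881e-02,2.967398e-02
6.143842e-01,7.969193e-02,2.956962e-02
6.671275e-01,7.683569e-02,2.941578e-02
7.243986e-01,7.403126e-02,2.921332e-02
7.865864e-01,7.127968e-02,2.896328e-02
8.541128e-01,6.858184e-02,2.866695e-02
9.274362e-01,6.593860e-02,2.832583e-02
1.007054e+00,6.335075e-02,2.794168e-02
1.093507e+00,6.081909e-02,2.751647e-02
1.187382e+00,5.834439e-02,2.705240e-02
1.289316e+00,5.592743e-02,2.655189e-02
1.400000e+00,5.356899e-02,2.601754e-02
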