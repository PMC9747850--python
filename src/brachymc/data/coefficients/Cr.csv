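# generated by scripts/make_coefficient_tables.py
# element Cr (Z=24); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,1.916542e+02,1.914795e+02
1.085847e-02,1.448031e+02,1.446292e+02
1.179065e-02,1.095808e+02,1.094078e+02
1.280284e-02,8.306152e+01,8.288949e+01
1.390193e-02,6.306519e+01,6.289418e+01
1.509538e-02,4.796491e+01,4.779499e+01
1.639128e-02,3.654489e+01,3.637613e+01
1.779843e-02,2.789529e+01,2.772778e+01
1.932638e-02,2.133423e+01,2.116806e+01
1.999998e-02,1.909387e+01,1.892828e+01
2.000002e-02,1.909375e+01,1.892816e+01
2.098549e-02,1.634994e+01,1.618520e+01
2.278704e-02,1.255780e+01,1.239458e+01
2.474325e-02,9.668298e+00,9.506685e+00
2.686740e-02,7.463220e+00,7.303321e+00
2.917389e-02,5.777858e+00,5.619777e+00
3.167840e-02,4.487707e+00,4.331550e+00
3.439791e-02,3.498521e+00,3.344397e+00
3.735088e-02,2.738855e+00,2.586875e+00
4.055735e-02,2.154473e+00,2.004749e+00
4.403910e-02,1.704143e+00,1.556788e+00
4.781974e-02,1.356476e+00,1.211603e+00
5.192494e-02,1.087542e+00,9.452621e-01
5.638256e-02,8.790708e-01,7.394945e-01
6.122286e-02,7.170951e-01,5.803297e-01
6.647868e-02,5.909217e-01,4.570708e-01
7.218571e-02,4.923526e-01,3.615153e-01
7.611092e-02,4.405680e-01,3.117178e-01
7.611108e-02,4.405662e-01,3.117161e-01
7.838266e-02,4.150946e-01,2.873642e-01
8.511161e-02,3.543101e-01,2.297732e-01
9.241822e-02,3.062757e-01,1.850112e-01
1.003521e-01,2.681218e-01,1.502003e-01
1.089671e-01,2.376346e-01,1.231171e-01
1.183216e-01,2.131037e-01,1.020417e-01
1.284792e-01,1.932069e-01,8.564104e-02
1.395088e-01,1.769207e-01,7.288089e-02
1.514853e-01,1.634522e-01,6.295731e-02
1.644899e-01,1.521868e-01,5.524457e-02
1.786109e-01,1.426477e-01,4.925489e-02
1.939442e-01,1.344648e-01,4.460750e-02
2.105938e-01,1.273508e-01,4.100476e-02
2.286728e-01,1.210825e-01,3.821372e-02
2.483037e-01,1.154863e-01,3.605184e-02
2.696199e-01,1.104274e-01,3.437593e-02
2.927661e-01,1.058008e-01,3.307353e-02
3.178993e-01,1.015249e-01,3.205627e-02
3.451902e-01,9.753578e-02,3.125465e-02
3.748239e-01,9.378393e-02,3.061394e-02
4.070015e-01,9.023043e-02,3.009108e-02
4.419415e-01,8.684487e-02,2.965215e-02
4.798811e-01,8.360334e-02,2.927044e-02
5.210776e-01,8.048706e-02,2.892498e-02
5.658108e-01,7.748118e-02,2.859930e-02
6.143842e-01,7.457400e-02,2.828056e-02
6.671275e-01,7.175626e-02,2.795879e-02
7.243986e-01,6.902065e-02,2.762637e-02
7.865864e-01,6.636141e-02,2.727758e-02
8.541128e-01,6.377400e-02,2.690822e-02
9.274362e-01,6.125492e-02,2.651541e-02
1.007054e+00,5.880146e-02,2.609731e-02
1.093507e+00,5.641160e-02,2.565298e-02
1.187382e+00,5.408382e-02,2.518224e-02
1.289316e+00,5.181705e-02,2.468552e-02
1.400000e+00,4.961058e-02,2.416380e-02
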