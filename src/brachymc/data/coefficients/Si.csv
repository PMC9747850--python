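# generated by scripts/make_coefficient_tables.py
# element Si (Z=14); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,3.598996e+01,3.580130e+01
1.085847e-02,2.719753e+01,2.700976e+01
1.179065e-02,2.059515e+01,2.040834e+01
1.280284e-02,1.562990e+01,1.544411e+01
1.390193e-02,1.189021e+01,1.170552e+01
1.509538e-02,9.069335e+00,8.885824e+00
1.639128e-02,6.938293e+00,6.756044e+00
1.779843e-02,5.325919e+00,5.145020e+00
1.932638e-02,4.104083e+00,3.924626e+00
1.999998e-02,3.687153e+00,3.508324e+00
2.000002e-02,3.687130e+00,3.508301e+00
2.098549e-02,3.176729e+00,2.998810e+00
2.278704e-02,2.471745e+00,2.295465e+00
2.474325e-02,1.934917e+00,1.760379e+00
2.686740e-02,1.525425e+00,1.352739e+00
2.917389e-02,1.212494e+00,1.041772e+00
3.167840e-02,9.728878e-01,8.042432e-01
3.439791e-02,7.890348e-01,6.225859e-01
3.735088e-02,6.476309e-01,4.834972e-01
4.055735e-02,5.385872e-01,3.768900e-01
4.403910e-02,4.542428e-01,2.951038e-01
4.781974e-02,3.887720e-01,2.323130e-01
5.192494e-02,3.377386e-01,1.840804e-01
5.638256e-02,2.977599e-01,1.470214e-01
6.122286e-02,2.662532e-01,1.185504e-01
6.647868e-02,2.412440e-01,9.668890e-02
7.218571e-02,2.212212e-01,7.992066e-02
7.611092e-02,2.104312e-01,7.127667e-02
7.611108e-02,2.104308e-01,7.127637e-02
7.838266e-02,2.050269e-01,6.708172e-02
8.511161e-02,1.917733e-01,5.727694e-02
9.241822e-02,1.807789e-01,4.981675e-02
1.003521e-01,1.715208e-01,4.416886e-02
1.089671e-01,1.635972e-01,3.992164e-02
1.183216e-01,1.566999e-01,3.675608e-02
1.284792e-01,1.505926e-01,3.442448e-02
1.395088e-01,1.450941e-01,3.273410e-02
1.514853e-01,1.400663e-01,3.153464e-02
1.644899e-01,1.354035e-01,3.070871e-02
1.786109e-01,1.310260e-01,3.016444e-02
1.939442e-01,1.268732e-01,2.982985e-02
2.105938e-01,1.228998e-01,2.964845e-02
2.286728e-01,1.190719e-01,2.957592e-02
2.483037e-01,1.153645e-01,2.957745e-02
2.696199e-01,1.117592e-01,2.962570e-02
2.927661e-01,1.082427e-01,2.969924e-02
3.178993e-01,1.048054e-01,2.978130e-02
3.451902e-01,1.014405e-01,2.985876e-02
3.748239e-01,9.814318e-02,2.992140e-02
4.070015e-01,9.491009e-02,2.996131e-02
4.419415e-01,9.173888e-02,2.997237e-02
4.798811e-01,8.862793e-02,2.994995e-02
5.210776e-01,8.557611e-02,2.989054e-02
5.658108e-01,8.258265e-02,2.979162e-02
6.143842e-01,7.964702e-02,2.965142e-02
6.671275e-01,7.676885e-02,2.946883e-02
7.243986e-01,7.394796e-02,2.924331e-02
7.865864e-01,7.118425e-02,2.897483e-02
8.541128e-01,6.847776e-02,2.866378e-02
9.274362e-01,6.582864e-02,2.831096e-02
1.007054e+00,6.323713e-02,2.791757e-02
1.093507e+00,6.070354e-02,2.748511e-02
1.187382e+00,5.822832e-02,2.701543e-02
1.289316e+00,5.581193e-02,2.651065e-02
1.400000e+00,5.345492e-02,2.597313e-02
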