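# generated by scripts/make_coefficient_tables.py
# element Mn (Z=25); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,2.157649e+02,2.155926e+02
1.085847e-02,1.630287e+02,1.628573e+02
1.179065e-02,1.233785e+02,1.232080e+02
1.280284e-02,9.352280e+01,9.335319e+01
1.390193e-02,7.100867e+01,7.084007e+01
1.509538e-02,5.400556e+01,5.383803e+01
1.639128e-02,4.114534e+01,4.097897e+01
1.779843e-02,3.140409e+01,3.123895e+01
1.932638e-02,2.401434e+01,2.385052e+01
1.999998e-02,2.149086e+01,2.132761e+01
2.000002e-02,2.149072e+01,2.132747e+01
2.098549e-02,1.840005e+01,1.823764e+01
2.278704e-02,1.412825e+01,1.396733e+01
2.474325e-02,1.087301e+01,1.071368e+01
2.686740e-02,8.388656e+00,8.231014e+00
2.917389e-02,6.489717e+00,6.333868e+00
3.167840e-02,5.035996e+00,4.882044e+00
3.439791e-02,3.921354e+00,3.769406e+00
3.735088e-02,3.065323e+00,2.915489e+00
4.055735e-02,2.406814e+00,2.259204e+00
4.403910e-02,1.899382e+00,1.754107e+00
4.781974e-02,1.507663e+00,1.364835e+00
5.192494e-02,1.204696e+00,1.064425e+00
5.638256e-02,9.698965e-01,8.322904e-01
6.122286e-02,7.875238e-01,6.526889e-01
6.647868e-02,6.455272e-01,5.135658e-01
7.218571e-02,5.346672e-01,4.056768e-01
7.611092e-02,4.764654e-01,3.494341e-01
7.611108e-02,4.764634e-01,3.494321e-01
7.838266e-02,4.478498e-01,3.219224e-01
8.511161e-02,3.796215e-01,2.568425e-01
9.241822e-02,3.257841e-01,2.062314e-01
1.003521e-01,2.831019e-01,1.668449e-01
1.089671e-01,2.490777e-01,1.361768e-01
1.183216e-01,2.217822e-01,1.122879e-01
1.284792e-01,1.997234e-01,9.367590e-02
1.395088e-01,1.817459e-01,7.917469e-02
1.514853e-01,1.669544e-01,6.787808e-02
1.644899e-01,1.546545e-01,5.908074e-02
1.786109e-01,1.443073e-01,5.223287e-02
1.939442e-01,1.354942e-01,4.690531e-02
2.105938e-01,1.278898e-01,4.276259e-02
2.286728e-01,1.212412e-01,3.954219e-02
2.483037e-01,1.153516e-01,3.703836e-02
2.696199e-01,1.100677e-01,3.508972e-02
2.927661e-01,1.052702e-01,3.356953e-02
3.178993e-01,1.008661e-01,3.237814e-02
3.451902e-01,9.678269e-02,3.143718e-02
3.748239e-01,9.296322e-02,3.068494e-02
4.070015e-01,8.936323e-02,3.007280e-02
4.419415e-01,8.594787e-02,2.956247e-02
4.798811e-01,8.268972e-02,2.912378e-02
5.210776e-01,7.956720e-02,2.873298e-02
5.658108e-01,7.656327e-02,2.837140e-02
6.143842e-01,7.366443e-02,2.802446e-02
6.671275e-01,7.086003e-02,2.768080e-02
7.243986e-01,6.814163e-02,2.733167e-02
7.865864e-01,6.550255e-02,2.697043e-02
8.541128e-01,6.293757e-02,2.659218e-02
9.274362e-01,6.044258e-02,2.619344e-02
1.007054e+00,5.801441e-02,2.577190e-02
1.093507e+00,5.565066e-02,2.532623e-02
1.187382e+00,5.334951e-02,2.485590e-02
1.289316e+00,5.110965e-02,2.436111e-02
1.400000e+00,4.893015e-02,2.384257e-02
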