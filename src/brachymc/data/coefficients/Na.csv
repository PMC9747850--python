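# generated by scripts/make_coefficient_tables.py
# element Na (Z=11); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,1.586151e+01,1.568042e+01
1.085847e-02,1.200428e+01,1.182405e+01
1.179065e-02,9.109266e+00,8.929953e+00
1.280284e-02,6.933148e+00,6.754819e+00
1.390193e-02,5.294913e+00,5.117640e+00
1.509538e-02,4.059712e+00,3.883570e+00
1.639128e-02,3.126936e+00,2.952006e+00
1.779843e-02,2.421419e+00,2.247784e+00
1.932638e-02,1.886918e+00,1.714668e+00
1.999998e-02,1.704550e+00,1.532902e+00
2.000002e-02,1.704540e+00,1.532892e+00
2.098549e-02,1.481294e+00,1.310520e+00
2.278704e-02,1.172926e+00,1.003725e+00
2.474325e-02,9.380534e-01,7.705251e-01
2.686740e-02,7.587944e-01,5.930431e-01
2.917389e-02,6.216743e-01,4.578074e-01
3.167840e-02,5.165236e-01,3.546513e-01
3.439791e-02,4.356563e-01,2.758915e-01
3.735088e-02,3.732555e-01,2.157130e-01
4.055735e-02,3.249120e-01,1.697080e-01
4.403910e-02,2.872794e-01,1.345310e-01
4.781974e-02,2.578143e-01,1.076383e-01
5.192494e-02,2.345810e-01,8.709328e-02
5.638256e-02,2.161043e-01,7.141906e-02
6.122286e-02,2.012588e-01,5.948736e-02
6.647868e-02,1.891850e-01,5.043483e-02
7.218571e-02,1.792258e-01,4.359955e-02
7.611092e-02,1.737008e-01,4.013433e-02
7.611108e-02,1.737006e-01,4.013421e-02
7.838266e-02,1.708788e-01,3.847306e-02
8.511161e-02,1.637593e-01,3.466395e-02
9.241822e-02,1.575733e-01,3.187021e-02
1.003521e-01,1.520961e-01,2.985826e-02
1.089671e-01,1.471560e-01,2.844696e-02
1.183216e-01,1.426227e-01,2.749546e-02
1.284792e-01,1.383971e-01,2.689395e-02
1.395088e-01,1.344045e-01,2.655653e-02
1.514853e-01,1.305892e-01,2.641589e-02
1.644899e-01,1.269097e-01,2.641913e-02
1.786109e-01,1.233358e-01,2.652457e-02
1.939442e-01,1.198457e-01,2.669938e-02
2.105938e-01,1.164242e-01,2.691761e-02
2.286728e-01,1.130609e-01,2.715883e-02
2.483037e-01,1.097490e-01,2.740691e-02
2.696199e-01,1.064844e-01,2.764918e-02
2.927661e-01,1.032651e-01,2.787571e-02
3.178993e-01,1.000901e-01,2.807874e-02
3.451902e-01,9.695947e-02,2.825226e-02
3.748239e-01,9.387383e-02,2.839165e-02
4.070015e-01,9.083402e-02,2.849339e-02
4.419415e-01,8.784101e-02,2.855487e-02
4.798811e-01,8.489581e-02,2.857417e-02
5.210776e-01,8.199937e-02,2.854998e-02
5.658108e-01,7.915254e-02,2.848145e-02
6.143842e-01,7.635610e-02,2.836818e-02
6.671275e-01,7.361072e-02,2.821013e-02
7.243986e-01,7.091701e-02,2.800758e-02
7.865864e-01,6.827556e-02,2.776115e-02
8.541128e-01,6.568689e-02,2.747172e-02
9.274362e-01,6.315157e-02,2.714050e-02
1.007054e+00,6.067016e-02,2.676894e-02
1.093507e+00,5.824324e-02,2.635877e-02
1.187382e+00,5.587142e-02,2.591196e-02
1.289316e+00,5.355535e-02,2.543072e-02
1.400000e+00,5.129567e-02,2.491746e-02
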