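# generated by scripts/make_coefficient_tables.py
# element Fe (Z=26); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,2.507750e+02,2.505988e+02
1.085847e-02,1.894927e+02,1.893173e+02
1.179065e-02,1.434130e+02,1.432385e+02
1.280284e-02,1.087130e+02,1.085395e+02
1.390193e-02,8.254363e+01,8.237114e+01
1.509538e-02,6.277830e+01,6.260691e+01
1.639128e-02,4.782764e+01,4.765743e+01
1.779843e-02,3.650199e+01,3.633303e+01
1.932638e-02,2.790960e+01,2.774199e+01
1.999998e-02,2.497527e+01,2.480825e+01
2.000002e-02,2.497511e+01,2.480809e+01
2.098549e-02,2.138110e+01,2.121493e+01
2.278704e-02,1.641330e+01,1.624866e+01
2.474325e-02,1.262740e+01,1.246439e+01
2.686740e-02,9.737854e+00,9.576570e+00
2.917389e-02,7.529064e+00,7.369613e+00
3.167840e-02,5.838043e+00,5.680534e+00
3.439791e-02,4.541395e+00,4.385936e+00
3.735088e-02,3.545559e+00,3.392262e+00
4.055735e-02,2.779498e+00,2.628477e+00
4.403910e-02,2.189201e+00,2.040569e+00
4.781974e-02,1.733542e+00,1.587413e+00
5.192494e-02,1.381161e+00,1.237648e+00
5.638256e-02,1.108113e+00,9.673270e-01
6.122286e-02,8.960889e-01,7.581381e-01
6.647868e-02,7.310681e-01,5.960572e-01
7.218571e-02,6.023002e-01,4.703290e-01
7.611092e-02,5.347356e-01,4.047687e-01
7.611108e-02,5.347332e-01,4.047664e-01
7.838266e-02,5.015307e-01,3.726933e-01
8.511161e-02,4.224128e-01,2.967965e-01
9.241822e-02,3.600604e-01,2.377449e-01
1.003521e-01,3.107068e-01,1.917632e-01
1.089671e-01,2.714447e-01,1.559347e-01
1.183216e-01,2.400275e-01,1.280029e-01
1.284792e-01,2.147173e-01,1.062192e-01
1.395088e-01,1.941681e-01,8.922658e-02
1.514853e-01,1.773364e-01,7.597049e-02
1.644899e-01,1.634125e-01,6.563010e-02
1.786109e-01,1.517678e-01,5.756560e-02
1.939442e-01,1.419137e-01,5.127758e-02
2.105938e-01,1.334701e-01,4.637571e-02
2.286728e-01,1.261415e-01,4.255448e-02
2.483037e-01,1.196974e-01,3.957449e-02
2.696199e-01,1.139586e-01,3.724794e-02
2.927661e-01,1.087850e-01,3.542732e-02
3.178993e-01,1.040673e-01,3.399665e-02
3.451902e-01,9.972029e-02,3.286470e-02
3.748239e-01,9.567707e-02,3.195960e-02
4.070015e-01,9.188528e-02,3.122471e-02
4.419415e-01,8.830380e-02,3.061540e-02
4.798811e-01,8.490026e-02,3.009647e-02
5.210776e-01,8.164914e-02,2.964019e-02
5.658108e-01,7.853027e-02,2.922474e-02
6.143842e-01,7.552769e-02,2.883303e-02
6.671275e-01,7.262876e-02,2.845171e-02
7.243986e-01,6.982347e-02,2.807043e-02
7.865864e-01,6.710388e-02,2.768132e-02
8.541128e-01,6.446377e-02,2.727848e-02
9.274362e-01,6.189822e-02,2.685763e-02
1.007054e+00,5.940343e-02,2.641583e-02
1.093507e+00,5.697648e-02,2.595128e-02
1.187382e+00,5.461516e-02,2.546309e-02
1.289316e+00,5.231781e-02,2.495113e-02
1.400000e+00,5.008324e-02,2.441592e-02
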