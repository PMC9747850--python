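# generated by scripts/make_coefficient_tables.py
# element Mg (Z=12); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,2.166142e+01,2.147457e+01
1.085847e-02,1.638198e+01,1.619600e+01
1.179065e-02,1.241883e+01,1.223380e+01
1.280284e-02,9.439314e+00,9.255299e+00
1.390193e-02,7.195905e+00,7.012979e+00
1.509538e-02,5.504165e+00,5.322407e+00
1.639128e-02,4.226468e+00,4.045960e+00
1.779843e-02,3.259967e+00,3.080796e+00
1.932638e-02,2.527700e+00,2.349957e+00
1.999998e-02,2.277852e+00,2.100731e+00
2.000002e-02,2.277838e+00,2.100717e+00
2.098549e-02,1.971989e+00,1.795769e+00
2.278704e-02,1.549546e+00,1.374949e+00
2.474325e-02,1.227838e+00,1.054967e+00
2.686740e-02,9.823779e-01,8.113414e-01
2.917389e-02,7.947099e-01,6.256179e-01
3.167840e-02,6.509026e-01,4.838688e-01
3.439791e-02,5.404252e-01,3.755660e-01
3.735088e-02,4.553062e-01,2.927403e-01
4.055735e-02,3.895028e-01,2.293499e-01
4.403910e-02,3.384275e-01,1.808085e-01
4.781974e-02,2.985933e-01,1.436286e-01
5.192494e-02,2.673454e-01,1.151548e-01
5.638256e-02,2.426605e-01,9.336180e-02
6.122286e-02,2.229945e-01,7.670251e-02
6.647868e-02,2.071676e-01,6.399321e-02
7.218571e-02,1.942775e-01,5.432654e-02
7.611092e-02,1.872128e-01,4.938736e-02
7.611108e-02,1.872125e-01,4.938719e-02
7.838266e-02,1.836334e-01,4.700573e-02
8.511161e-02,1.747064e-01,4.149469e-02
9.241822e-02,1.670914e-01,3.738010e-02
1.003521e-01,1.604781e-01,3.434256e-02
1.089671e-01,1.546290e-01,3.213473e-02
1.183216e-01,1.493628e-01,3.056458e-02
1.284792e-01,1.445412e-01,2.948265e-02
1.395088e-01,1.400592e-01,2.877235e-02
1.514853e-01,1.358375e-01,2.834249e-02
1.644899e-01,1.318165e-01,2.812161e-02
1.786109e-01,1.279518e-01,2.805360e-02
1.939442e-01,1.242108e-01,2.809433e-02
2.105938e-01,1.205697e-01,2.820908e-02
2.286728e-01,1.170116e-01,2.837050e-02
2.483037e-01,1.135247e-01,2.855710e-02
2.696199e-01,1.101010e-01,2.875196e-02
2.927661e-01,1.067351e-01,2.894185e-02
3.178993e-01,1.034239e-01,2.911640e-02
3.451902e-01,1.001656e-01,2.926757e-02
3.748239e-01,9.695930e-02,2.938912e-02
4.070015e-01,9.380472e-02,2.947628e-02
4.419415e-01,9.070199e-02,2.952543e-02
4.798811e-01,8.765141e-02,2.953387e-02
5.210776e-01,8.465339e-02,2.949969e-02
5.658108e-01,8.170837e-02,2.942155e-02
6.143842e-01,7.881677e-02,2.929869e-02
6.671275e-01,7.597902e-02,2.913077e-02
7.243986e-01,7.319552e-02,2.891786e-02
7.865864e-01,7.046667e-02,2.866040e-02
8.541128e-01,6.779290e-02,2.835919e-02
9.274362e-01,6.517466e-02,2.801532e-02
1.007054e+00,6.261243e-02,2.763022e-02
1.093507e+00,6.010674e-02,2.720559e-02
1.187382e+00,5.765817e-02,2.674341e-02
1.289316e+00,5.526733e-02,2.624591e-02
1.400000e+00,5.293485e-02,2.571553e-02
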