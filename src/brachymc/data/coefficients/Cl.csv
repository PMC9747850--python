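# generated by scripts/make_coefficient_tables.py
# element Cl (Z=17); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,6.495911e+01,6.477762e+01
1.085847e-02,4.907154e+01,4.889090e+01
1.179065e-02,3.713636e+01,3.695664e+01
1.280284e-02,2.815694e+01,2.797820e+01
1.390193e-02,2.139119e+01,2.121351e+01
1.509538e-02,1.628574e+01,1.610920e+01
1.639128e-02,1.242738e+01,1.225206e+01
1.779843e-02,9.507075e+00,9.333048e+00
1.932638e-02,7.293404e+00,7.120765e+00
1.999998e-02,6.537875e+00,6.365840e+00
2.000002e-02,6.537833e+00,6.365798e+00
2.098549e-02,5.612809e+00,5.441649e+00
2.278704e-02,4.334936e+00,4.165353e+00
2.474325e-02,3.361747e+00,3.193840e+00
2.686740e-02,2.619397e+00,2.453272e+00
2.917389e-02,2.052189e+00,1.887953e+00
3.167840e-02,1.618052e+00,1.455814e+00
3.439791e-02,1.285160e+00,1.125034e+00
3.735088e-02,1.029406e+00,8.715078e-01
4.055735e-02,8.325026e-01,6.769484e-01
4.403910e-02,6.805572e-01,5.274641e-01
4.781974e-02,5.630011e-01,4.124862e-01
5.192494e-02,4.717830e-01,3.239625e-01
5.638256e-02,4.007608e-01,2.557490e-01
6.122286e-02,3.452424e-01,2.031510e-01
6.647868e-02,3.016389e-01,1.625757e-01
7.218571e-02,2.672015e-01,1.312692e-01
7.611092e-02,2.488999e-01,1.150320e-01
7.611108e-02,2.488993e-01,1.150315e-01
7.838266e-02,2.398222e-01,1.071177e-01
8.511161e-02,2.178827e-01,8.849605e-02
9.241822e-02,2.001393e-01,7.415252e-02
1.003521e-01,1.856353e-01,6.312165e-02
1.089671e-01,1.736344e-01,5.465739e-02
1.183216e-01,1.635693e-01,4.818230e-02
1.284792e-01,1.550033e-01,4.324860e-02
1.395088e-01,1.475998e-01,3.950848e-02
1.514853e-01,1.410997e-01,3.669130e-02
1.644899e-01,1.353035e-01,3.458612e-02
1.786109e-01,1.300580e-01,3.302828e-02
1.939442e-01,1.252456e-01,3.188904e-02
2.105938e-01,1.207762e-01,3.106763e-02
2.286728e-01,1.165810e-01,3.048511e-02
2.483037e-01,1.126074e-01,3.007957e-02
2.696199e-01,1.088156e-01,2.980244e-02
2.927661e-01,1.051751e-01,2.961561e-02
3.178993e-01,1.016630e-01,2.948919e-02
3.451902e-01,9.826199e-02,2.939973e-02
3.748239e-01,9.495884e-02,2.932888e-02
4.070015e-01,9.174358e-02,2.926227e-02
4.419415e-01,8.860864e-02,2.918871e-02
4.798811e-01,8.554825e-02,2.909951e-02
5.210776e-01,8.255799e-02,2.898797e-02
5.658108e-01,7.963444e-02,2.884900e-02
6.143842e-01,7.677499e-02,2.867878e-02
6.671275e-01,7.397762e-02,2.847458e-02
7.243986e-01,7.124079e-02,2.823453e-02
7.865864e-01,6.856337e-02,2.795753e-02
8.541128e-01,6.594452e-02,2.764311e-02
9.274362e-01,6.338371e-02,2.729136e-02
1.007054e+00,6.088060e-02,2.690288e-02
1.093507e+00,5.843509e-02,2.647867e-02
1.187382e+00,5.604723e-02,2.602016e-02
1.289316e+00,5.371719e-02,2.552909e-02
1.400000e+00,5.144525e-02,2.500752e-02
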