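# generated by scripts/make_coefficient_tables.py
# element S (Z=16); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,5.553451e+01,5.534563e+01
1.085847e-02,4.195461e+01,4.176662e+01
1.179065e-02,3.175434e+01,3.156730e+01
1.280284e-02,2.408117e+01,2.389516e+01
1.390193e-02,1.830037e+01,1.811547e+01
1.509538e-02,1.393872e+01,1.375500e+01
1.639128e-02,1.064286e+01,1.046040e+01
1.779843e-02,8.148588e+00,7.967480e+00
1.932638e-02,6.258062e+00,6.078397e+00
1.999998e-02,5.612867e+00,5.433831e+00
2.000002e-02,5.612832e+00,5.433795e+00
2.098549e-02,4.822929e+00,4.644804e+00
2.278704e-02,3.731786e+00,3.555302e+00
2.474325e-02,2.900853e+00,2.726113e+00
2.686740e-02,2.267034e+00,2.094148e+00
2.917389e-02,1.782746e+00,1.611826e+00
3.167840e-02,1.412050e+00,1.243210e+00
3.439791e-02,1.127764e+00,9.611224e-01
3.735088e-02,9.093007e-01,7.449769e-01
4.055735e-02,7.410435e-01,5.791589e-01
4.403910e-02,6.111313e-01,4.518079e-01
4.781974e-02,5.105417e-01,3.539014e-01
5.192494e-02,4.324023e-01,2.785661e-01
5.638256e-02,3.714711e-01,2.205580e-01
6.122286e-02,3.237444e-01,1.758705e-01
6.647868e-02,2.861600e-01,1.414374e-01
7.218571e-02,2.563733e-01,1.149090e-01
7.611092e-02,2.404864e-01,1.011707e-01
7.611108e-02,2.404858e-01,1.011702e-01
7.838266e-02,2.325864e-01,9.448142e-02
8.511161e-02,2.134199e-01,7.876770e-02
9.241822e-02,1.978136e-01,6.669972e-02
1.003521e-01,1.849529e-01,5.745344e-02
1.089671e-01,1.742108e-01,5.039199e-02
1.183216e-01,1.651051e-01,4.502228e-02
1.284792e-01,1.572645e-01,4.096182e-02
1.395088e-01,1.504036e-01,3.791342e-02
1.514853e-01,1.443030e-01,3.564569e-02
1.644899e-01,1.387943e-01,3.397819e-02
1.786109e-01,1.337484e-01,3.276999e-02
1.939442e-01,1.290666e-01,3.191086e-02
2.105938e-01,1.246738e-01,3.131444e-02
2.286728e-01,1.205127e-01,3.091306e-02
2.483037e-01,1.165400e-01,3.065364e-02
2.696199e-01,1.127232e-01,3.049453e-02
2.927661e-01,1.090375e-01,3.040304e-02
3.178993e-01,1.054646e-01,3.035356e-02
3.451902e-01,1.019907e-01,3.032602e-02
3.748239e-01,9.860552e-02,3.030470e-02
4.070015e-01,9.530140e-02,3.027737e-02
4.419415e-01,9.207256e-02,3.023449e-02
4.798811e-01,8.891468e-02,3.016871e-02
5.210776e-01,8.582448e-02,3.007439e-02
5.658108e-01,8.279948e-02,2.994729e-02
6.143842e-01,7.983780e-02,2.978428e-02
6.671275e-01,7.693802e-02,2.958319e-02
7.243986e-01,7.409906e-02,2.934262e-02
7.865864e-01,7.132017e-02,2.906184e-02
8.541128e-01,6.860082e-02,2.874071e-02
9.274362e-01,6.594073e-02,2.837958e-02
1.007054e+00,6.333978e-02,2.797930e-02
1.093507e+00,6.079803e-02,2.754111e-02
1.187382e+00,5.831566e-02,2.706661e-02
1.289316e+00,5.589298e-02,2.655775e-02
1.400000e+00,5.353038e-02,2.601674e-02
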