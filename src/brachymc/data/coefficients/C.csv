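# generated by scripts/make_coefficient_tables.py
# element C (Z=6); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,2.470034e+00,2.280975e+00
1.085847e-02,1.906837e+00,1.718669e+00
1.179065e-02,1.484529e+00,1.297318e+00
1.280284e-02,1.167332e+00,9.811487e-01
1.390193e-02,9.286622e-01,7.435814e-01
1.509538e-02,7.487413e-01,5.648420e-01
1.639128e-02,6.128311e-01,4.301967e-01
1.779843e-02,5.099336e-01,3.286518e-01
1.932638e-02,4.318298e-01,2.519929e-01
1.999998e-02,4.051250e-01,2.259173e-01
2.000002e-02,4.051235e-01,2.259158e-01
2.098549e-02,3.723686e-01,1.940730e-01
2.278704e-02,3.269396e-01,1.502860e-01
2.474325e-02,2.920820e-01,1.171752e-01
2.686740e-02,2.651941e-01,9.214263e-02
2.917389e-02,2.443173e-01,7.323316e-02
3.167840e-02,2.279746e-01,5.897296e-02
3.439791e-02,2.150507e-01,4.824939e-02
3.735088e-02,2.047022e-01,4.022111e-02
4.055735e-02,1.962904e-01,3.425086e-02
4.403910e-02,1.893309e-01,2.985501e-02
4.781974e-02,1.834561e-01,2.666582e-02
5.192494e-02,1.783864e-01,2.440296e-02
5.638256e-02,1.739098e-01,2.285219e-02
6.122286e-02,1.698647e-01,2.184925e-02
6.647868e-02,1.661289e-01,2.126772e-02
7.218571e-02,1.626095e-01,2.100987e-02
7.611092e-02,1.604281e-01,2.097896e-02
7.611108e-02,1.604280e-01,2.097896e-02
7.838266e-02,1.592370e-01,2.099974e-02
8.511161e-02,1.559590e-01,2.117796e-02
9.241822e-02,1.527372e-01,2.149774e-02
1.003521e-01,1.495435e-01,2.192200e-02
1.089671e-01,1.463584e-01,2.242103e-02
1.183216e-01,1.431687e-01,2.297089e-02
1.284792e-01,1.399661e-01,2.355210e-02
1.395088e-01,1.367466e-01,2.414870e-02
1.514853e-01,1.335089e-01,2.474754e-02
1.644899e-01,1.302543e-01,2.533778e-02
1.786109e-01,1.269855e-01,2.591041e-02
1.939442e-01,1.237068e-01,2.645801e-02
2.105938e-01,1.204232e-01,2.697446e-02
2.286728e-01,1.171402e-01,2.745478e-02
2.483037e-01,1.138636e-01,2.789493e-02
2.696199e-01,1.105990e-01,2.829169e-02
2.927661e-01,1.073523e-01,2.864255e-02
3.178993e-01,1.041285e-01,2.894559e-02
3.451902e-01,1.009327e-01,2.919937e-02
3.748239e-01,9.776912e-02,2.940290e-02
4.070015e-01,9.464181e-02,2.955552e-02
4.419415e-01,9.155414e-02,2.965686e-02
4.798811e-01,8.850903e-02,2.970682e-02
5.210776e-01,8.550896e-02,2.970550e-02
5.658108e-01,8.255602e-02,2.965322e-02
6.143842e-01,7.965193e-02,2.955049e-02
6.671275e-01,7.679816e-02,2.939800e-02
7.243986e-01,7.399593e-02,2.919665e-02
7.865864e-01,7.124633e-02,2.894754e-02
8.541128e-01,6.855029e-02,2.865201e-02
9.274362e-01,6.590869e-02,2.831158e-02
1.007054e+00,6.332237e-02,2.792803e-02
1.093507e+00,6.079212e-02,2.750336e-02
1.187382e+00,5.831874e-02,2.703978e-02
1.289316e+00,5.590303e-02,2.653972e-02
1.400000e+00,5.354577e-02,2.600579e-02
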