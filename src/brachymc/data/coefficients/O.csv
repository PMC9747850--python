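# generated by scripts/make_coefficient_tables.py
# element O (Z=8); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,6.005709e+00,5.816465e+00
1.085847e-02,4.571956e+00,4.383604e+00
1.179065e-02,3.496493e+00,3.309099e+00
1.280284e-02,2.688522e+00,2.502157e+00
1.390193e-02,2.080544e+00,1.895282e+00
1.509538e-02,1.622305e+00,1.438225e+00
1.639128e-02,1.276336e+00,1.093523e+00
1.779843e-02,1.014664e+00,8.332050e-01
1.932638e-02,8.163713e-01,6.363582e-01
1.999998e-02,7.486879e-01,5.693047e-01
2.000002e-02,7.486842e-01,5.693010e-01
2.098549e-02,6.657940e-01,4.873238e-01
2.278704e-02,5.511870e-01,3.743604e-01
2.474325e-02,4.637294e-01,2.886514e-01
2.686740e-02,3.967875e-01,2.235666e-01
2.917389e-02,3.453648e-01,1.741132e-01
3.167840e-02,3.056927e-01,1.365256e-01
3.439791e-02,2.749246e-01,1.079599e-01
3.735088e-02,2.509069e-01,8.626472e-02
4.055735e-02,2.320086e-01,6.981031e-02
4.403910e-02,2.169921e-01,5.736002e-02
4.781974e-02,2.049176e-01,4.797388e-02
5.192494e-02,1.950705e-01,4.093619e-02
5.638256e-02,1.869065e-01,3.570097e-02
6.122286e-02,1.800112e-01,3.185080e-02
6.647868e-02,1.740688e-01,2.906580e-02
7.218571e-02,1.688385e-01,2.710021e-02
7.611092e-02,1.657649e-01,2.617925e-02
7.611108e-02,1.657648e-01,2.617922e-02
7.838266e-02,1.641372e-01,2.576464e-02
8.511161e-02,1.598257e-01,2.491264e-02
9.241822e-02,1.557985e-01,2.443053e-02
1.003521e-01,1.519762e-01,2.422973e-02
1.089671e-01,1.482996e-01,2.424085e-02
1.183216e-01,1.447248e-01,2.440932e-02
1.284792e-01,1.412200e-01,2.469199e-02
1.395088e-01,1.377628e-01,2.505459e-02
1.514853e-01,1.343377e-01,2.546976e-02
1.644899e-01,1.309349e-01,2.591563e-02
1.786109e-01,1.275487e-01,2.637465e-02
1.939442e-01,1.241767e-01,2.683270e-02
2.105938e-01,1.208187e-01,2.727849e-02
2.286728e-01,1.174762e-01,2.770297e-02
2.483037e-01,1.141517e-01,2.809893e-02
2.696199e-01,1.108486e-01,2.846066e-02
2.927661e-01,1.075705e-01,2.878372e-02
3.178993e-01,1.043212e-01,2.906466e-02
3.451902e-01,1.011044e-01,2.930084e-02
3.748239e-01,9.792347e-02,2.949031e-02
4.070015e-01,9.478171e-02,2.963169e-02
4.419415e-01,9.168189e-02,2.972401e-02
4.798811e-01,8.862649e-02,2.976670e-02
5.210776e-01,8.561762e-02,2.975951e-02
5.658108e-01,8.265706e-02,2.970246e-02
6.143842e-01,7.974632e-02,2.959582e-02
6.671275e-01,7.688669e-02,2.944011e-02
7.243986e-01,7.407925e-02,2.923609e-02
7.865864e-01,7.132494e-02,2.898474e-02
8.541128e-01,6.862464e-02,2.868729e-02
9.274362e-01,6.597914e-02,2.834522e-02
1.007054e+00,6.338922e-02,2.796022e-02
1.093507e+00,6.085562e-02,2.753427e-02
1.187382e+00,5.837912e-02,2.706952e-02
1.289316e+00,5.596046e-02,2.656839e-02
1.400000e+00,5.360042e-02,2.603347e-02
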