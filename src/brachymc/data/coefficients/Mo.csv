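# generated by scripts/make_coefficient_tables.py
# element Mo (Z=42); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,2.041193e+02,2.039536e+02
1.085847e-02,1.544103e+02,1.542454e+02
1.179065e-02,1.169933e+02,1.168293e+02
1.280284e-02,8.878679e+01,8.862365e+01
1.390193e-02,6.749195e+01,6.732977e+01
1.509538e-02,5.139122e+01,5.123008e+01
1.639128e-02,3.919957e+01,3.903953e+01
1.779843e-02,2.995415e+01,2.979530e+01
1.932638e-02,2.293250e+01,2.277492e+01
1.999998e-02,2.053273e+01,2.037570e+01
2.000002e-02,1.121962e+02,1.120392e+02
2.098549e-02,9.602417e+01,9.586793e+01
2.278704e-02,7.365294e+01,7.349814e+01
2.474325e-02,5.658725e+01,5.643399e+01
2.686740e-02,4.354947e+01,4.339783e+01
2.917389e-02,3.357406e+01,3.342415e+01
3.167840e-02,2.593033e+01,2.578224e+01
3.439791e-02,2.006449e+01,1.991833e+01
3.735088e-02,1.555624e+01,1.541211e+01
4.055735e-02,1.208614e+01,1.194415e+01
4.403910e-02,9.411065e+00,9.271323e+00
4.781974e-02,7.345701e+00,7.208312e+00
5.192494e-02,5.748602e+00,5.613673e+00
5.638256e-02,4.511650e+00,4.379285e+00
6.122286e-02,3.552089e+00,3.422390e+00
6.647868e-02,2.806483e+00,2.679548e+00
7.218571e-02,2.226139e+00,2.102061e+00
7.611092e-02,1.922513e+00,1.800320e+00
7.611108e-02,1.922503e+00,1.800309e+00
7.838266e-02,1.773624e+00,1.652493e+00
8.511161e-02,1.420128e+00,1.302025e+00
9.241822e-02,1.143440e+00,1.028441e+00
1.003521e-01,9.264167e-01,8.145872e-01
1.089671e-01,7.558051e-01,6.472039e-01
1.183216e-01,6.213485e-01,5.160242e-01
1.284792e-01,5.150966e-01,4.130878e-01
1.395088e-01,4.308792e-01,3.322143e-01
1.514853e-01,3.639012e-01,2.685981e-01
1.644899e-01,3.104313e-01,2.184974e-01
1.786109e-01,2.675622e-01,1.789943e-01
1.939442e-01,2.330258e-01,1.478107e-01
2.105938e-01,2.050504e-01,1.231651e-01
2.286728e-01,1.822502e-01,1.036626e-01
2.483037e-01,1.635403e-01,8.820958e-02
2.696199e-01,1.480697e-01,7.594721e-02
2.927661e-01,1.351705e-01,6.620045e-02
3.178993e-01,1.243175e-01,5.843782e-02
3.451902e-01,1.150973e-01,5.224041e-02
3.748239e-01,1.071841e-01,4.727759e-02
4.070015e-01,1.003205e-01,4.328810e-02
4.419415e-01,9.430324e-02,4.006523e-02
4.798811e-01,8.897119e-02,3.744525e-02
5.210776e-01,8.419663e-02,3.529837e-02
5.658108e-01,7.987812e-02,3.352159e-02
6.143842e-01,7.593497e-02,3.203315e-02
6.671275e-01,7.230292e-02,3.076812e-02
7.243986e-01,6.893073e-02,2.967497e-02
7.865864e-01,6.577751e-02,2.871285e-02
8.541128e-01,6.281063e-02,2.784943e-02
9.274362e-01,6.000401e-02,2.705922e-02
1.007054e+00,5.733683e-02,2.632225e-02
1.093507e+00,5.479250e-02,2.562294e-02
1.187382e+00,5.235775e-02,2.494930e-02
1.289316e+00,5.002207e-02,2.429221e-02
1.400000e+00,4.777706e-02,2.364492e-02
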