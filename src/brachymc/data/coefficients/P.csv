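# generated by scripts/make_coefficient_tables.py
# element P (Z=15); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,4.371704e+01,4.353376e+01
1.085847e-02,3.303064e+01,3.284822e+01
1.179065e-02,2.500487e+01,2.482338e+01
1.280284e-02,1.896830e+01,1.878780e+01
1.390193e-02,1.442109e+01,1.424166e+01
1.509538e-02,1.099062e+01,1.081234e+01
1.639128e-02,8.398736e+00,8.221682e+00
1.779843e-02,6.437449e+00,6.261707e+00
1.932638e-02,4.951056e+00,4.776715e+00
1.999998e-02,4.443818e+00,4.270087e+00
2.000002e-02,4.443790e+00,4.270059e+00
2.098549e-02,3.822812e+00,3.649965e+00
2.278704e-02,2.965061e+00,2.793805e+00
2.474325e-02,2.311889e+00,2.142327e+00
2.686740e-02,1.813666e+00,1.645903e+00
2.917389e-02,1.432966e+00,1.267110e+00
3.167840e-02,1.141526e+00,9.776886e-01
3.439791e-02,9.179730e-01,7.562688e-01
3.735088e-02,7.461209e-01,5.866660e-01
4.055735e-02,6.136939e-01,4.566059e-01
4.403910e-02,5.113688e-01,3.567661e-01
4.781974e-02,4.320552e-01,2.800562e-01
5.192494e-02,3.703530e-01,2.210749e-01
5.638256e-02,3.221435e-01,1.757020e-01
6.122286e-02,2.842819e-01,1.407895e-01
6.647868e-02,2.543632e-01,1.139287e-01
7.218571e-02,2.305463e-01,9.327360e-02
7.611092e-02,2.177857e-01,8.259784e-02
7.611108e-02,2.177852e-01,8.259747e-02
7.838266e-02,2.114201e-01,7.740707e-02
8.511161e-02,1.959019e-01,6.523947e-02
9.241822e-02,1.831606e-01,5.593153e-02
1.003521e-01,1.725573e-01,4.883563e-02
1.089671e-01,1.636012e-01,4.345111e-02
1.183216e-01,1.559150e-01,3.939021e-02
1.284792e-01,1.492087e-01,3.635201e-02
1.395088e-01,1.432597e-01,3.410253e-02
1.514853e-01,1.378974e-01,3.245953e-02
1.644899e-01,1.329912e-01,3.128076e-02
1.786109e-01,1.284415e-01,3.045504e-02
1.939442e-01,1.241724e-01,2.989533e-02
2.105938e-01,1.201266e-01,2.953341e-02
2.286728e-01,1.162606e-01,2.931579e-02
2.483037e-01,1.125421e-01,2.920048e-02
2.696199e-01,1.089467e-01,2.915453e-02
2.927661e-01,1.054566e-01,2.915209e-02
3.178993e-01,1.020584e-01,2.917290e-02
3.451902e-01,9.874240e-02,2.920113e-02
3.748239e-01,9.550148e-02,2.922439e-02
4.070015e-01,9.233045e-02,2.923306e-02
4.419415e-01,8.922550e-02,2.921967e-02
4.798811e-01,8.618385e-02,2.917851e-02
5.210776e-01,8.320344e-02,2.910521e-02
5.658108e-01,8.028275e-02,2.899656e-02
6.143842e-01,7.742067e-02,2.885022e-02
6.671275e-01,7.461638e-02,2.866466e-02
7.243986e-01,7.186928e-02,2.843896e-02
7.865864e-01,6.917899e-02,2.817277e-02
8.541128e-01,6.654531e-02,2.786624e-02
9.274362e-01,6.396817e-02,2.751995e-02
1.007054e+00,6.144765e-02,2.713490e-02
1.093507e+00,5.898395e-02,2.671243e-02
1.187382e+00,5.657737e-02,2.625423e-02
1.289316e+00,5.422831e-02,2.576227e-02
1.400000e+00,5.193721e-02,2.523879e-02
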