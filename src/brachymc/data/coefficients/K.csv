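# generated by scripts/make_coefficient_tables.py
# element K (Z=19); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,9.445110e+01,9.426718e+01
1.085847e-02,7.134854e+01,7.116549e+01
1.179065e-02,5.398906e+01,5.380694e+01
1.280284e-02,4.092557e+01,4.074445e+01
1.390193e-02,3.108025e+01,3.090021e+01
1.509538e-02,2.364925e+01,2.347035e+01
1.639128e-02,1.803210e+01,1.785443e+01
1.779843e-02,1.377969e+01,1.360333e+01
1.932638e-02,1.055558e+01,1.038063e+01
1.999998e-02,9.455025e+00,9.280690e+00
2.000002e-02,9.454964e+00,9.280629e+00
2.098549e-02,8.107395e+00,7.933948e+00
2.278704e-02,6.245559e+00,6.073709e+00
2.474325e-02,4.827441e+00,4.657291e+00
2.686740e-02,3.745593e+00,3.577248e+00
2.917389e-02,2.918949e+00,2.752517e+00
3.167840e-02,2.286261e+00,2.121855e+00
3.439791e-02,1.801189e+00,1.638923e+00
3.735088e-02,1.428622e+00,1.268614e+00
4.055735e-02,1.141919e+00,9.842861e-01
4.403910e-02,9.208371e-01,7.656977e-01
4.781974e-02,7.499717e-01,5.974449e-01
5.192494e-02,6.175859e-01,4.677896e-01
5.638256e-02,5.147234e-01,3.677735e-01
6.122286e-02,4.345408e-01,2.905502e-01
6.647868e-02,3.718014e-01,2.308794e-01
7.218571e-02,3.224936e-01,1.847443e-01
7.611092e-02,2.964232e-01,1.607660e-01
7.611108e-02,2.964223e-01,1.607652e-01
7.838266e-02,2.835394e-01,1.490612e-01
8.511161e-02,2.525750e-01,1.214589e-01
9.241822e-02,2.277825e-01,1.001117e-01
1.003521e-01,2.077625e-01,8.361127e-02
1.089671e-01,1.914368e-01,7.086960e-02
1.183216e-01,1.779742e-01,6.104484e-02
1.284792e-01,1.667329e-01,5.348445e-02
1.395088e-01,1.572179e-01,4.768182e-02
1.514853e-01,1.490469e-01,4.324301e-02
1.644899e-01,1.419247e-01,3.986116e-02
1.786109e-01,1.356235e-01,3.729693e-02
1.939442e-01,1.299677e-01,3.536332e-02
2.105938e-01,1.248217e-01,3.391409e-02
2.286728e-01,1.200814e-01,3.283471e-02
2.483037e-01,1.156663e-01,3.203541e-02
2.696199e-01,1.115150e-01,3.144576e-02
2.927661e-01,1.075799e-01,3.101051e-02
3.178993e-01,1.038248e-01,3.068627e-02
3.451902e-01,1.002216e-01,3.043896e-02
3.748239e-01,9.674904e-02,3.024186e-02
4.070015e-01,9.339043e-02,3.007399e-02
4.419415e-01,9.013307e-02,2.991893e-02
4.798811e-01,8.696709e-02,2.976385e-02
5.210776e-01,8.388481e-02,2.959878e-02
5.658108e-01,8.088025e-02,2.941601e-02
6.143842e-01,7.794874e-02,2.920967e-02
6.671275e-01,7.508664e-02,2.897540e-02
7.243986e-01,7.229110e-02,2.871001e-02
7.865864e-01,6.955996e-02,2.841138e-02
8.541128e-01,6.689155e-02,2.807820e-02
9.274362e-01,6.428467e-02,2.770991e-02
1.007054e+00,6.173848e-02,2.730660e-02
1.093507e+00,5.925243e-02,2.686887e-02
1.187382e+00,5.682624e-02,2.639782e-02
1.289316e+00,5.445981e-02,2.589496e-02
1.400000e+00,5.215323e-02,2.536212e-02
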