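# generated by scripts/make_coefficient_tables.py
# element Ni (Z=28); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,3.269824e+02,3.268019e+02
1.085847e-02,2.471063e+02,2.469266e+02
1.179065e-02,1.870357e+02,1.868569e+02
1.280284e-02,1.417926e+02,1.416148e+02
1.390193e-02,1.076664e+02,1.074897e+02
1.509538e-02,8.188735e+01,8.171172e+01
1.639128e-02,6.238470e+01,6.221029e+01
1.779843e-02,4.760841e+01,4.743529e+01
1.932638e-02,3.639639e+01,3.622464e+01
1.999998e-02,3.256701e+01,3.239587e+01
2.000002e-02,3.256680e+01,3.239566e+01
2.098549e-02,2.787617e+01,2.770590e+01
2.278704e-02,2.139182e+01,2.122312e+01
2.474325e-02,1.644947e+01,1.628244e+01
2.686740e-02,1.267675e+01,1.251148e+01
2.917389e-02,9.792482e+00,9.629098e+00
3.167840e-02,7.584076e+00,7.422681e+00
3.439791e-02,5.890541e+00,5.731247e+00
3.735088e-02,4.589800e+00,4.432722e+00
4.055735e-02,3.589150e+00,3.434404e+00
4.403910e-02,2.818093e+00,2.665795e+00
4.781974e-02,2.222942e+00,2.073209e+00
5.192494e-02,1.762754e+00,1.615701e+00
5.638256e-02,1.406260e+00,1.262001e+00
6.122286e-02,1.129547e+00,9.881939e-01
6.647868e-02,9.143016e-01,7.759604e-01
7.218571e-02,7.464774e-01,6.112509e-01
7.611092e-02,6.584978e-01,5.253250e-01
7.611108e-02,6.584947e-01,5.253221e-01
7.838266e-02,6.152882e-01,4.832728e-01
8.511161e-02,5.124390e-01,3.837242e-01
9.241822e-02,4.315421e-01,3.062095e-01
1.003521e-01,3.676723e-01,2.457948e-01
1.089671e-01,3.170269e-01,1.986677e-01
1.183216e-01,2.766665e-01,1.618786e-01
1.284792e-01,2.443162e-01,1.331418e-01
1.395088e-01,2.182134e-01,1.106833e-01
1.514853e-01,1.969909e-01,9.312466e-02
1.644899e-01,1.795872e-01,7.939277e-02
1.786109e-01,1.651772e-01,6.865131e-02
1.939442e-01,1.531193e-01,6.024747e-02
2.105938e-01,1.429138e-01,5.367099e-02
2.286728e-01,1.341714e-01,4.852255e-02
2.483037e-01,1.265885e-01,4.448918e-02
2.696199e-01,1.199282e-01,4.132535e-02
2.927661e-01,1.140053e-01,3.883820e-02
3.178993e-01,1.086751e-01,3.687605e-02
3.451902e-01,1.038242e-01,3.531951e-02
3.748239e-01,9.936369e-02,3.407451e-02
4.070015e-01,9.522377e-02,3.306689e-02
4.419415e-01,9.134951e-02,3.223812e-02
4.798811e-01,8.769764e-02,3.154201e-02
5.210776e-01,8.423395e-02,3.094210e-02
5.658108e-01,8.093140e-02,3.040966e-02
6.143842e-01,7.776854e-02,2.992208e-02
6.671275e-01,7.472838e-02,2.946161e-02
7.243986e-01,7.179740e-02,2.901445e-02
7.865864e-01,6.896492e-02,2.856993e-02
8.541128e-01,6.622246e-02,2.811993e-02
9.274362e-01,6.356335e-02,2.765842e-02
1.007054e+00,6.098236e-02,2.718106e-02
1.093507e+00,5.847542e-02,2.668492e-02
1.187382e+00,5.603940e-02,2.616824e-02
1.289316e+00,5.367192e-02,2.563019e-02
1.400000e+00,5.137121e-02,2.507076e-02
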