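# generated by scripts/make_coefficient_tables.py
# element V (Z=23); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,1.632475e+02,1.630766e+02
1.085847e-02,1.233342e+02,1.231641e+02
1.179065e-02,9.333050e+01,9.316129e+01
1.280284e-02,7.074249e+01,7.057422e+01
1.390193e-02,5.371202e+01,5.354474e+01
1.509538e-02,4.085258e+01,4.068637e+01
1.639128e-02,3.112816e+01,3.096309e+01
1.779843e-02,2.376347e+01,2.359962e+01
1.932638e-02,1.817755e+01,1.801501e+01
1.999998e-02,1.627029e+01,1.610832e+01
2.000002e-02,1.627019e+01,1.610822e+01
2.098549e-02,1.393443e+01,1.377328e+01
2.278704e-02,1.070644e+01,1.054678e+01
2.474325e-02,8.246993e+00,8.088909e+00
2.686740e-02,6.370238e+00,6.213832e+00
2.917389e-02,4.935906e+00,4.781278e+00
3.167840e-02,3.837974e+00,3.685228e+00
3.439791e-02,2.996194e+00,2.845437e+00
3.735088e-02,2.349739e+00,2.201078e+00
4.055735e-02,1.852436e+00,1.705982e+00
4.403910e-02,1.469187e+00,1.325050e+00
4.781974e-02,1.173274e+00,1.031565e+00
5.192494e-02,9.443317e-01,8.051591e-01
5.638256e-02,7.668115e-01,6.302833e-01
6.122286e-02,6.288281e-01,4.950495e-01
6.647868e-02,5.212834e-01,3.903556e-01
7.218571e-02,4.372029e-01,3.092229e-01
7.611092e-02,3.929934e-01,2.669571e-01
7.611108e-02,3.929919e-01,2.669557e-01
7.838266e-02,3.712331e-01,2.462922e-01
8.511161e-02,3.192596e-01,1.974424e-01
9.241822e-02,2.781158e-01,1.594996e-01
1.003521e-01,2.453618e-01,1.300155e-01
1.089671e-01,2.191156e-01,1.070991e-01
1.183216e-01,1.979237e-01,8.928709e-02
1.284792e-01,1.806625e-01,7.544571e-02
1.395088e-01,1.664628e-01,6.469508e-02
1.514853e-01,1.546515e-01,5.635131e-02
1.644899e-01,1.447072e-01,4.988205e-02
1.786109e-01,1.362255e-01,4.487229e-02
1.939442e-01,1.288930e-01,4.099804e-02
2.105938e-01,1.224664e-01,3.800603e-02
2.286728e-01,1.167571e-01,3.569804e-02
2.483037e-01,1.116185e-01,3.391873e-02
2.696199e-01,1.069369e-01,3.254624e-02
2.927661e-01,1.026240e-01,3.148490e-02
3.178993e-01,9.861101e-02,3.065952e-02
3.451902e-01,9.484464e-02,3.001099e-02
3.748239e-01,9.128324e-02,2.949280e-02
4.070015e-01,8.789433e-02,2.906833e-02
4.419415e-01,8.465251e-02,2.870880e-02
4.798811e-01,8.153790e-02,2.839155e-02
5.210776e-01,7.853485e-02,2.809881e-02
5.658108e-01,7.563104e-02,2.781667e-02
6.143842e-01,7.281675e-02,2.753429e-02
6.671275e-01,7.008433e-02,2.724333e-02
7.243986e-01,6.742772e-02,2.693743e-02
7.865864e-01,6.484216e-02,2.661186e-02
8.541128e-01,6.232393e-02,2.626325e-02
9.274362e-01,5.987018e-02,2.588933e-02
1.007054e+00,5.747870e-02,2.548876e-02
1.093507e+00,5.514788e-02,2.506098e-02
1.187382e+00,5.287653e-02,2.460612e-02
1.289316e+00,5.066385e-02,2.412483e-02
1.400000e+00,4.850931e-02,2.361825e-02
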