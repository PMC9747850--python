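# generated by scripts/make_coefficient_tables.py
# element H (Z=1); model: free-electron KN + parameterized photoelectric
# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g
1.000000e-02,3.959256e-01,2.046620e-02
1.085847e-02,3.913990e-01,1.770817e-02
1.179065e-02,3.876225e-01,1.583222e-02
1.280284e-02,3.843737e-01,1.462418e-02
1.390193e-02,3.814864e-01,1.392609e-02
1.509538e-02,3.788354e-01,1.362135e-02
1.639128e-02,3.763260e-01,1.362385e-02
1.779843e-02,3.738858e-01,1.386999e-02
1.932638e-02,3.714592e-01,1.431275e-02
1.999998e-02,3.704431e-01,1.454624e-02
2.000002e-02,3.704430e-01,1.454625e-02
2.098549e-02,3.690027e-01,1.491731e-02
2.278704e-02,3.664822e-01,1.565782e-02
2.474325e-02,3.638704e-01,1.651502e-02
2.686740e-02,3.611452e-01,1.747436e-02
2.917389e-02,3.582885e-01,1.852472e-02
3.167840e-02,3.552854e-01,1.965736e-02
3.439791e-02,3.521235e-01,2.086515e-02
3.735088e-02,3.487926e-01,2.214196e-02
4.055735e-02,3.452841e-01,2.348226e-02
4.403910e-02,3.415912e-01,2.488071e-02
4.781974e-02,3.377089e-01,2.633198e-02
5.192494e-02,3.336333e-01,2.783046e-02
5.638256e-02,3.293624e-01,2.937022e-02
6.122286e-02,3.248955e-01,3.094484e-02
6.647868e-02,3.202338e-01,3.254740e-02
7.218571e-02,3.153797e-01,3.417045e-02
7.611092e-02,3.121594e-01,3.522106e-02
7.611108e-02,3.121593e-01,3.522110e-02
7.838266e-02,3.103377e-01,3.580605e-02
8.511161e-02,3.051137e-01,3.744581e-02
9.241822e-02,2.997154e-01,3.908095e-02
1.003521e-01,2.941519e-01,4.070244e-02
1.089671e-01,2.884340e-01,4.230111e-02
1.183216e-01,2.825740e-01,4.386778e-02
1.284792e-01,2.765853e-01,4.539338e-02
1.395088e-01,2.704825e-01,4.686915e-02
1.514853e-01,2.642809e-01,4.828673e-02
1.644899e-01,2.579967e-01,4.963831e-02
1.786109e-01,2.516464e-01,5.091671e-02
1.939442e-01,2.452463e-01,5.211548e-02
2.105938e-01,2.388131e-01,5.322896e-02
2.286728e-01,2.323626e-01,5.425227e-02
2.483037e-01,2.259104e-01,5.518134e-02
2.696199e-01,2.194708e-01,5.601286e-02
2.927661e-01,2.130575e-01,5.674424e-02
3.178993e-01,2.066828e-01,5.737355e-02
3.451902e-01,2.003579e-01,5.789945e-02
3.748239e-01,1.940927e-01,5.832112e-02
4.070015e-01,1.878960e-01,5.863815e-02
4.419415e-01,1.817752e-01,5.885057e-02
4.798811e-01,1.757367e-01,5.895871e-02
5.210776e-01,1.697859e-01,5.896326e-02
5.658108e-01,1.639273e-01,5.886520e-02
6.143842e-01,1.581646e-01,5.866580e-02
6.671275e-01,1.525008e-01,5.836669e-02
7.243986e-01,1.469388e-01,5.796984e-02
7.865864e-01,1.414807e-01,5.747757e-02
8.541128e-01,1.361284e-01,5.689262e-02
9.274362e-01,1.308840e-01,5.621814e-02
1.007054e+00,1.257490e-01,5.545773e-02
1.093507e+00,1.207251e-01,5.461540e-02
1.187382e+00,1.158139e-01,5.369561e-02
1.289316e+00,1.110172e-01,5.270322e-02
1.400000e+00,1.063363e-01,5.164344e-02
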