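# Ir-192 photon emission spectrum (beta- to Pt-192, 95.13%; EC to Os-192, 4.87%)
# Discrete line table assembled from the standard evaluated nuclear data
# (ENSDF/NuDat gamma lines; Pt and Os K and L X-ray groups).
# Gamma-line energies and intensities carry the evaluated precision; the
# L X-ray group intensities (all below 13 keV, under or near the 10 keV
# transport cut) are approximate grouped values.
# columns: energy(MeV)  intensity(photons per decay)
7.822e-3    6.9e-4
8.266e-3    8.9e-4
8.911e-3    1.19e-2
9.442e-3    1.60e-2
1.0355e-2   7.2e-3
1.1071e-2   1.04e-2
1.2095e-2   1.2e-3
1.2942e-2   1.8e-3
6.1486e-2   1.20e-2
6.3000e-2   2.07e-2
6.5122e-2   2.63e-2
6.6831e-2   4.46e-2
7.1325e-2   8.1e-3
7.3590e-2   2.2e-3
7.5749e-2   1.53e-2
7.7850e-2   4.3e-3
1.10400e-1  1.22e-4
1.363426e-1 1.99e-3
1.76980e-1  4.3e-5
2.013112e-1 4.73e-3
2.057943e-1 3.34e-2
2.832668e-1 2.66e-3
2.959565e-1 2.871e-1
3.084551e-1 2.970e-1
3.165062e-1 8.286e-1
3.744852e-1 7.272e-3
4.164688e-1 6.70e-3
4.205200e-1 6.9e-4
4.680685e-1 4.784e-1
4.845751e-1 3.189e-2
4.890600e-1 4.38e-3
5.885810e-1 4.522e-2
6.044110e-1 8.216e-2
6.124622e-1 5.34e-2
8.845365e-1 2.91e-3
1.061480    5.31e-4
1.378200    1.2e-7
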