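t_s,q_m3s
0.000000,0.00000000e+00
0.012500,1.36755405e-05
0.025000,3.81849603e-05
0.037500,6.86526789e-05
0.050000,1.02530483e-04
0.062500,1.37742731e-04
0.075000,1.72435032e-04
0.087500,2.04926433e-04
0.100000,2.33718960e-04
0.112500,2.57525961e-04
0.125000,2.75304725e-04
0.137500,2.86286486e-04
0.150000,2.90000000e-04
0.162500,2.86286486e-04
0.175000,2.75304725e-04
0.187500,2.57525961e-04
0.200000,2.33718960e-04
0.212500,2.04926433e-04
0.225000,1.72435032e-04
0.237500,1.37742731e-04
0.250000,1.02530483e-04
0.262500,6.86526789e-05
0.275000,3.81849603e-05
0.287500,1.36755405e-05
0.300000,-7.58611398e-20
0.312500,-1.64046064e-05
0.325000,-2.89351425e-05
0.337500,-3.46324285e-05
0.350000,-3.21510077e-05
0.362500,-2.20768863e-05
0.375000,-6.78914321e-06
0.387500,8.17289365e-06
0.400000,7.36439101e-06
0.412500,6.63586940e-06
0.425000,5.97941673e-06
0.437500,5.38790356e-06
0.450000,4.85490577e-06
0.462500,4.37463473e-06
0.475000,3.94187445e-06
0.487500,3.55192494e-06
0.500000,3.20055114e-06
0.512500,2.88393696e-06
0.525000,2.59864380e-06
0.537500,2.34157323e-06
0.550000,2.10993335e-06
0.562500,1.90120842e-06
0.575000,1.71313157e-06
0.587500,1.54366021e-06
0.600000,1.39095379e-06
0.612500,1.25335383e-06
0.625000,1.12936594e-06
0.637500,1.01764353e-06
0.650000,9.16973254e-07
0.662500,8.26261772e-07
0.675000,7.44523913e-07
0.687500,6.70871964e-07
0.700000,6.04506026e-07
0.712500,5.44705331e-07
0.725000,4.90820414e-07
0.737500,4.42266056e-07
0.750000,3.98514933e-07
0.762500,3.59091886e-07
0.775000,3.23568759e-07
0.787500,2.91559754e-07
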