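SP,SI,A,W,E,N,H
spruce,6,6.97,0.73,0.68,17.74,35.09
spruce,8,5.45,0.57,0.53,13.88,27.43
spruce,11,7.10,0.75,0.69,18.07,35.77
spruce,14,7.16,0.76,0.70,18.23,36.06
spruce,17,7.94,0.84,0.78,20.21,39.99
spruce,20,8.17,0.86,0.80,20.78,41.12
spruce,23,8.36,0.88,0.82,21.29,42.11
pine,6,4.56,0.48,0.51,11.33,23.02
pine,8,5.64,0.60,0.63,13.98,28.43
pine,11,7.35,0.78,0.81,18.21,37.04
pine,14,8.35,0.88,0.92,20.68,42.05
pine,17,9.98,1.05,1.09,24.73,50.28
pine,20,11.81,1.25,1.29,29.25,59.45
birch,8,5.15,0.56,0.62,13.54,26.42
birch,11,7.34,0.79,0.90,19.33,37.66
birch,14,7.50,0.81,0.91,19.74,38.49
birch,17,8.67,0.94,1.06,22.84,44.49
birch,20,9.41,1.02,1.15,24.80,48.31
birch,23,14.06,1.52,1.74,37.16,72.27
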