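 position:            1 neighbors:          3

#predRMSD 0.000
 synth 001     1 A C  9999.000   -48.864  9999.000
 synth 001     2 D H   -56.055   -51.884   180.000
 synth 001     3 E H   -59.280   -46.534   180.000
 synth 001     4 F H   -61.333   -42.535   180.000
 synth 001     5 I H   -60.258   -47.714   180.000
 synth 001     6 K H   -60.979   -50.939   180.000
 synth 001     7 L H   -56.488   -49.007   180.000

#predRMSD 0.480
 synth 001     1 A C  9999.000   -47.337  9999.000
 synth 001     2 D H   -67.054   -61.365   180.000
 synth 001     3 E H   -64.357   -51.677   180.000
 synth 001     4 F H   -66.088   -44.562   180.000
 synth 001     5 I H   -59.160   -47.674   180.000
 synth 001     6 K H   -62.358   -53.937   180.000
 synth 001     7 L H   -55.433   -51.250   180.000

#predRMSD 0.374
 synth 001     1 A C  9999.000   -52.528  9999.000
 synth 001     2 D H   -61.586   -48.400   180.000
 synth 001     3 E H   -58.072   -42.189   180.000
 synth 001     4 F H   -52.458   -52.055   180.000
 synth 001     5 I H   -60.902   -43.944   180.000
 synth 001     6 K H   -56.579   -45.689   180.000
 synth 001     7 L H   -56.237   -52.068   180.000

 position:            2 neighbors:          3

#predRMSD 0.355
 synth 002     1 D H   -57.176   -47.765   180.000
 synth 002     2 E H   -55.026   -51.300   180.000
 synth 002     3 F H   -57.824   -43.683   180.000
 synth 002     4 I H   -54.570   -54.177   180.000
 synth 002     5 K H   -56.353   -49.183   180.000
 synth 002     6 L H   -53.453   -49.842   180.000
 synth 002     7 M C   -49.866  9999.000   180.000

#predRMSD 0.117
 synth 002     1 D H   -61.521   -50.624   180.000
 synth 002     2 E H   -54.675   -50.234   180.000
 synth 002     3 F H   -66.842   -36.702   180.000
 synth 002     4 I H   -60.300   -50.381   180.000
 synth 002     5 K H   -56.507   -47.805   180.000
 synth 002     6 L H   -50.504   -47.098   180.000
 synth 002     7 M C   -53.611  9999.000   180.000

#predRMSD 0.008
 synth 002     1 D H   -57.606   -48.808   180.000
 synth 002     2 E H   -60.127   -46.066   180.000
 synth 002     3 F H   -51.049   -50.774   180.000
 synth 002     4 I H   -54.719   -46.508   180.000
 synth 002     5 K H   -56.141   -54.727   180.000
 synth 002     6 L H   -53.447   -59.038   180.000
 synth 002     7 M C   -58.758  9999.000   180.000

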