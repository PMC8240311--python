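# fraglib-extended 1
target_length 8
fragment start 1 length 7 pred_rmsd 0.0000 source synth_001_000
R A C 9999.000 -48.864 9999.000 9999.000 9999.000 0.0000 0.0000 0.0000 1.4580 0.0000 0.0000 2.0095 1.4218 0.0000 2.8859 1.7579 -0.7964 1.9882 -0.7681 -1.2010
R D H -56.055 -51.884 180.000 93.104 44.950 1.4903 2.2525 0.8981 1.9294 3.6388 1.0033 1.7795 4.3674 -0.3280 2.7247 4.9849 -0.8185 3.3735 3.7031 1.4766
R E H -59.280 -46.534 180.000 92.280 48.471 0.5860 4.2909 -0.9076 0.3103 4.9424 -2.1825 1.2401 4.4288 -3.2767 1.8111 5.2108 -4.0369 0.4437 6.4514 -2.0465
R F H -61.333 -42.535 180.000 91.635 52.065 1.3873 3.1101 -3.3505 2.2475 2.4900 -4.3512 3.6965 2.9352 -4.1849 4.3833 3.2249 -5.1646 1.7548 2.8202 -5.7518
R I H -60.258 -47.714 180.000 92.873 46.071 4.1551 2.9873 -2.9386 5.5225 3.3971 -2.6419 5.7914 4.8162 -3.1311 6.8042 5.0778 -3.7802 6.5140 2.4293 -3.2695
R K H -60.979 -50.939 180.000 94.032 47.688 4.8782 5.7286 -2.8154 5.0150 7.1221 -3.2220 5.0523 7.2523 -4.7410 5.9458 7.8908 -5.2971 6.2682 7.7316 -2.6125
R L H -56.488 -49.007 180.000 92.331 9999.000 4.0764 6.6430 -5.4062 3.9959 6.6896 -6.8613 5.2759 6.1632 -7.5016 5.8445 6.7992 -8.3891 3.7197 8.1094 -7.3318
end
fragment start 1 length 7 pred_rmsd 0.4797 source synth_001_001
R A C 9999.000 -47.337 9999.000 9999.000 9999.000 0.0000 0.0000 0.0000 1.4580 0.0000 0.0000 2.0095 1.4218 0.0000 2.9055 1.7503 -0.7775 1.9882 -0.7681 -1.2010
R D H -67.054 -61.365 180.000 98.920 29.761 1.4682 2.2611 0.8769 1.9048 3.6484 0.9796 1.5401 4.4356 -0.2745 2.4142 4.9484 -0.9733 3.4046 3.7156 1.2233
R E H -64.357 -51.677 180.000 95.112 38.401 0.2439 4.5272 -0.5536 -0.2386 5.2516 -1.7233 0.2323 4.5906 -3.0143 0.7994 5.2467 -3.8880 0.2228 6.7002 -1.6773
R F H -66.088 -44.562 180.000 93.413 50.964 -0.0064 3.2881 -3.1277 0.3925 2.5362 -4.3114 1.9109 2.4736 -4.4391 2.4608 2.6680 -5.5232 -0.2138 3.1548 -5.5617
R I H -59.160 -47.674 180.000 92.589 44.384 2.5827 2.2010 -3.3253 4.0379 2.1123 -3.3106 4.6748 3.4200 -3.7689 5.5768 3.4222 -4.6066 4.5080 0.9637 -4.1899
R K H -62.358 -53.937 180.000 95.314 45.461 4.1994 4.5302 -3.2142 4.7211 5.8458 -3.5647 4.4867 6.1571 -5.0391 5.4206 6.4879 -5.7697 6.2045 5.9316 -3.2401
R L H -55.433 -51.250 180.000 92.757 9999.000 3.2340 6.0490 -5.4697 2.8747 6.3186 -6.8567 3.6987 5.4657 -7.8156 4.2990 5.9797 -8.7594 3.0606 7.7941 -7.1754
end
fragment start 1 length 7 pred_rmsd 0.3737 source synth_001_002
R A C 9999.000 -52.528 9999.000 9999.000 9999.000 0.0000 0.0000 0.0000 1.4580 0.0000 0.0000 2.0095 1.4218 0.0000 2.8372 1.7768 -0.8392 1.9882 -0.7681 -1.2010
R D H -61.586 -48.400 180.000 93.411 49.795 1.5453 2.2312 0.9464 1.9909 3.6150 1.0573 1.6395 4.4096 -0.1960 2.4823 5.1127 -0.7535 3.4896 3.6707 1.3105
R E H -58.072 -42.189 180.000 90.733 59.389 0.3901 4.2929 -0.6337 -0.0748 4.9996 -1.8212 0.7600 4.6326 -3.0436 1.1159 5.4956 -3.8460 -0.0369 6.5028 -1.5925
R F H -52.458 -52.055 180.000 92.288 44.064 1.0689 3.3471 -3.1787 1.8619 2.8638 -4.3027 3.1596 3.6527 -4.4417 3.4769 4.1594 -5.5178 1.0586 2.9441 -5.5917
R I H -60.902 -43.944 180.000 91.929 54.709 3.9058 3.7525 -3.3466 5.1697 4.4794 -3.3443 4.9618 5.9480 -3.6988 5.7164 6.5194 -4.4859 6.1510 3.8397 -4.3145
R K H -56.579 -45.689 180.000 91.369 52.616 3.9340 6.5533 -3.1127 3.6251 7.9556 -3.3653 3.4160 8.2148 -4.8535 3.9388 9.1838 -5.4041 4.7338 8.8478 -2.8283
R L H -56.237 -52.068 180.000 93.206 9999.000 2.6484 7.3427 -5.4988 2.3689 7.4755 -6.9236 3.6583 7.5249 -7.7363 3.8595 8.4312 -8.5447 1.5353 8.7202 -7.1865
end
fragment start 2 length 7 pred_rmsd 0.3553 source synth_002_000
R D H -57.176 -47.765 180.000 92.127 51.924 1.5038 2.2473 0.9105 1.9445 3.6330 1.0172 1.7492 4.3768 -0.2997 2.6533 5.0630 -0.7762 3.4035 3.6941 1.4425
R E H -55.026 -51.300 180.000 92.674 47.544 0.5633 4.2358 -0.8829 0.2472 4.8936 -2.1451 1.2701 4.5435 -3.2206 1.8247 5.4269 -3.8744 0.1810 6.4012 -1.9553
R F H -57.824 -43.683 180.000 91.095 55.647 1.5151 3.2495 -3.3985 2.4711 2.7805 -4.3944 3.8552 3.3732 -4.1522 4.5280 3.8063 -5.0877 1.9903 3.1268 -5.7952
R I H -54.570 -54.177 180.000 93.458 45.285 4.2742 3.3891 -2.8911 5.5781 3.9282 -2.5237 5.7474 5.3562 -3.0315 6.7146 5.6675 -3.7265 6.6898 3.0434 -3.0665
R K H -56.353 -49.183 180.000 92.351 52.440 4.8007 6.2201 -2.6799 4.8433 7.6159 -3.0991 4.9207 7.7336 -4.6175 5.7598 8.4588 -5.1516 6.0250 8.3265 -2.4571
R L H -53.453 -49.842 180.000 91.849 9999.000 4.0402 7.0158 -5.3073 4.0072 7.0383 -6.7648 5.3778 6.7191 -7.3524 5.8766 7.4400 -8.2166 3.5254 8.3921 -7.2633
R M C -49.866 9999.000 180.000 9999.000 9999.000 5.9814 5.6343 -6.8779 7.2947 5.2178 -7.3550 8.2835 6.3785 -7.3319 9.4478 6.2220 -7.6997 7.1911 4.6451 -8.7603
end
fragment start 2 length 7 pred_rmsd 0.1168 source synth_002_001
R D H -61.521 -50.624 180.000 94.071 49.473 1.4783 2.2572 0.8867 1.9160 3.6440 0.9906 1.6593 4.4021 -0.3075 2.5539 5.0569 -0.8425 3.3920 3.7085 1.3524
R E H -54.675 -50.234 180.000 92.262 41.384 0.4320 4.3086 -0.8087 0.0555 4.9848 -2.0443 0.9941 4.6099 -3.1863 1.5177 5.4792 -3.8831 0.0504 6.4925 -1.8432
R F H -66.842 -36.702 180.000 91.427 56.642 1.2023 3.3105 -3.3722 2.0776 2.8183 -4.4292 3.5296 3.2037 -4.1669 4.2777 3.5108 -5.0950 1.6291 3.3529 -5.7807
R I H -60.300 -50.381 180.000 93.691 48.449 3.9214 3.1852 -2.8971 5.2837 3.5323 -2.5106 5.6258 4.9611 -2.9193 6.6570 5.2081 -3.5445 6.2748 2.5584 -3.1291
R K H -56.507 -47.805 180.000 91.975 57.053 4.7539 5.8984 -2.5620 4.9619 7.3035 -2.8907 5.1320 7.4990 -4.3935 6.0540 8.1817 -4.8399 6.1743 7.8473 -2.1506
R L H -50.504 -47.098 180.000 90.331 9999.000 4.2370 6.8955 -5.1688 4.2864 7.0021 -6.6220 5.6784 6.6747 -7.1520 6.2238 7.4019 -7.9821 3.8707 8.3962 -7.0658
R M C -53.611 9999.000 180.000 9999.000 9999.000 6.2476 5.5762 -6.6668 7.5763 5.1508 -7.0904 8.5953 6.2723 -6.9188 9.7760 6.1033 -7.2235 7.5475 4.6855 -8.5382
end
fragment start 2 length 7 pred_rmsd 0.0084 source synth_002_002
R D H -57.606 -48.808 180.000 92.545 46.949 1.3844 2.2936 0.7845 1.8111 3.6847 0.8765 1.7949 4.3581 -0.4917 2.7639 5.0063 -0.8867 3.2008 3.7737 1.4882
R E H -60.127 -46.066 180.000 92.353 57.189 0.6881 4.2001 -1.2103 0.5437 4.7921 -2.5349 1.6135 4.2739 -3.4902 2.2380 5.0471 -4.2165 0.6090 6.3091 -2.4476
R F H -51.049 -50.774 180.000 91.560 50.859 1.8196 2.9610 -3.4839 2.8137 2.3373 -4.3492 4.1677 3.0269 -4.2199 4.7821 3.4016 -5.2187 2.3478 2.3638 -5.7968
R I H -54.719 -46.508 180.000 91.158 51.698 4.6269 3.1912 -2.9837 5.9082 3.8356 -2.7216 5.9745 5.2147 -3.3690 6.9638 5.5611 -4.0146 7.0513 2.9659 -3.2221
R K H -56.141 -54.727 180.000 94.016 45.917 4.9153 5.9976 -3.1918 4.8513 7.3397 -3.7580 5.0599 7.3116 -5.2684 5.9357 7.9967 -5.7966 5.8858 8.2416 -3.1024
R L H -53.447 -59.038 180.000 94.744 9999.000 4.2497 6.5151 -5.9579 4.3438 6.3963 -7.4080 5.7634 6.0463 -7.8416 6.3909 6.7850 -8.6005 3.8947 7.6869 -8.0760
R M C -58.758 9999.000 180.000 9999.000 9999.000 6.2636 4.9154 -7.3547 7.6091 4.4655 -7.6908 8.6539 5.4994 -7.2843 9.8514 5.2988 -7.4870 7.7136 4.1718 -9.1795
end
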