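compound_id,ie,ea,mu,chi,softness,eta,omega,nucleophilicity,dipole,polarizability
4a,7.135,0.766,-3.951,3.951,0.157,6.369,1.225,3.247,1.456,329.99
4b,7.19,0.922,-4.056,4.056,0.16,6.267,1.312,3.167,2.026,349.79
4c,7.404,1.515,-4.459,4.459,0.17,5.889,1.688,2.992,5.538,360.34
4d,7.103,0.697,-3.9,3.9,0.156,6.407,1.187,3.309,0.738,314.76
4e,7.16,0.857,-4.009,4.009,0.159,6.303,1.275,3.227,2.026,334.40
4f,7.378,1.471,-4.425,4.425,0.169,5.907,1.657,3.051,5.774,345.30
4g,7.198,0.774,-3.986,3.986,0.156,6.423,1.237,3.2,1.934,325.50
4h,7.252,0.928,-4.09,4.09,0.158,6.324,1.323,3.116,2.96,345.15
4i,7.479,1.517,-4.498,4.498,0.168,5.962,1.697,2.926,6.33,355.36
4j,7.131,0.621,-3.876,3.876,0.154,6.51,1.154,3.301,0.903,312.93
4k,7.187,0.789,-3.988,3.988,0.156,6.398,1.243,3.215,2.805,332.58
4l,7.417,1.427,-4.422,4.422,0.167,5.99,1.632,3.021,6.5456,343.83
ascorbic_acid,8.69,-1.452,-3.619,3.619,0.099,10.142,0.646,2.713,8.697,83.65
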