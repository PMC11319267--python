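compound_id,phase,site,bde,ip,pde,pa,ete,setpt,splet
4k,water,N22-H,80.37,115.44,160.31,30.59,89.17,275.75,119.76
4k,water,C19-H,105.87,115.44,185.81,84.01,61.25,301.25,145.26
4k,methanol,N22-H,80.34,111.01,157.78,34.27,83.42,268.79,117.69
4k,methanol,C19-H,105.89,111.01,183.33,88.07,55.17,294.35,143.24
4k,cyclohexane,N22-H,79.63,151.61,192.5,119.77,91.9,344.11,211.67
4k,cyclohexane,C19-H,106.19,151.61,219.06,181.28,56.95,370.67,238.23
ascorbic_acid,water,O1-H,72.96,127.24,133.88,277.03,84.4,261.12,361.43
ascorbic_acid,water,O12-H,105.87,65.74,141.1,32.18,80.17,206.84,112.35
ascorbic_acid,methanol,O1-H,73.02,123.23,130.82,277.72,78.52,254.05,356.23
ascorbic_acid,methanol,O12-H,105.89,65.59,138.25,35.95,74.42,203.84,110.37
ascorbic_acid,cyclohexane,O1-H,73.8,172.64,154.87,296.9,82.06,327.51,378.96
ascorbic_acid,cyclohexane,O12-H,106.19,63.03,165.65,126.09,79.76,228.68,205.85
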