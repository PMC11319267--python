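compound_id,site,bde,ip,pde,pa,ete,setpt,splet
4a,N21-H,78.15,167.13,228.86,321.93,73.33,395.99,395.26
4a,C18-H,106.37,167.13,257.08,385.74,37.73,424.21,423.48
4b,N22-H,78.22,168.42,227.65,320.26,75.08,396.07,395.33
4b,C19-H,106.4,168.42,255.83,384.08,39.43,424.25,423.51
4c,N25-H,78.38,173.27,222.96,316.44,79.05,396.23,395.49
4c,C22-H,106.46,173.27,251.04,379.69,43.88,424.31,423.57
4d,N21-H,77.67,169.05,226.46,335.2,59.58,395.51,394.78
4d,C18-H,106.27,169.05,255.06,387.2,36.17,424.11,423.38
4e,N22-H,77.75,170.3,225.29,322.37,72.49,395.59,394.86
4e,C19-H,106.31,170.3,253.85,385.49,37.93,424.15,423.42
4f,N22-H,77.9,175.21,220.53,318.34,76.67,395.74,395
4f,C12-H,107.93,175.21,250.57,385.29,39.75,425.77,425.04
4g,N21-H,77.55,171.15,224.24,319.54,75.11,395.39,394.65
4g,C18-H,106.45,171.15,253.15,385.31,38.25,424.3,423.56
4h,N22-H,77.68,172.35,223.17,317.92,76.87,395.52,394.79
4h,C19-H,106.5,172.35,251.99,383.63,39.98,424.34,423.61
4i,N16-H,77.91,177.44,218.32,314.2,80.82,395.75,395.02
4i,C26-H,106.56,177.44,246.97,379.27,44.4,424.41,423.67
4j,N21-H,79.05,169.67,227.23,322.68,73.49,396.9,396.16
4j,C18-H,106.3,169.67,254.47,389.29,34.12,424.14,423.41
4k,N22-H,79.14,167.82,229.16,320.94,75.31,396.98,396.25
4k,C19-H,106.34,167.82,256.37,387.5,35.96,424.19,423.45
4l,N16-H,79.33,176.07,221.11,317.01,79.43,397.18,396.44
4l,C18-H,106.42,176.07,248.19,382.56,40.97,424.26,423.53
ascorbic_acid,O1-H,61.71,196.57,182.99,320.03,58.8,379.56,378.82
ascorbic_acid,O12-H,74.27,196.57,195.55,333.99,57.39,392.11,391.38
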