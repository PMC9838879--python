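metric,subtype,input,output,mean,sem,n
auc,I,ACC,ACC,980.57,234.03,15
auc,I,ACC,plPFC,1726.36,500.26,15
auc,I,ACC,ilPFC,874.5,158.12,15
auc,I,ACC,OFC,365.18,97.84,15
auc,I,ACC,RSC,543.90,100.59,15
auc,I,ACC,V1/V2,1187.82,339.33,15
auc,I,ACC,PtA,2612.2,499.74,15
auc,I,plPFC,ACC,1110.11,329.41,15
auc,I,plPFC,plPFC,829.25,283.61,15
auc,I,plPFC,ilPFC,-126.12,75.50,15
auc,I,plPFC,OFC,910.73,253.03,15
auc,I,plPFC,RSC,-5.03,37.58,15
auc,I,plPFC,V1/V2,2063.42,642.18,15
auc,I,plPFC,PtA,2857.86,1006.19,15
auc,I,ilPFC,ACC,90.03,10.76,15
auc,I,ilPFC,plPFC,-87.94,34.25,15
auc,I,ilPFC,ilPFC,418.33,82.48,15
auc,I,ilPFC,OFC,921.15,214.65,15
auc,I,ilPFC,RSC,948.56,203.32,15
auc,I,ilPFC,V1/V2,585.93,95.61,15
auc,I,ilPFC,PtA,425.83,69.29,15
auc,I,OFC,ACC,558.56,120.27,15
auc,I,OFC,plPFC,391.55,72.17,15
auc,I,OFC,ilPFC,437.82,79.15,15
auc,I,OFC,OFC,334.97,56.41,15
auc,I,OFC,RSC,260.83,40.83,15
auc,I,OFC,V1/V2,514.24,135.05,15
auc,I,OFC,PtA,318.96,51.90,15
auc,I,aINS,ACC,133.14,24.28,15
auc,I,aINS,plPFC,126.87,25.88,15
auc,I,aINS,ilPFC,361.20,66.63,15
auc,I,aINS,OFC,170.44,20.30,15
auc,I,aINS,RSC,259.51,46.23,15
auc,I,aINS,V1/V2,97.69,21.15,15
auc,I,aINS,PtA,261.55,54.64,15
auc,II,ACC,ACC,1888.64,621.51,15
auc,II,ACC,plPFC,2283.24,718.96,15
auc,II,ACC,ilPFC,1630.08,437.59,15
auc,II,ACC,OFC,1092.71,369.70,15
auc,II,ACC,RSC,1018.83,228.81,15
auc,II,ACC,V1/V2,1387.44,427.60,15
auc,II,ACC,PtA,1846.68,611.11,15
auc,II,plPFC,ACC,1448.17,422.10,15
auc,II,plPFC,plPFC,1397.84,400.05,15
auc,II,plPFC,ilPFC,257.79,33.61,15
auc,II,plPFC,OFC,711.19,171.64,15
auc,II,plPFC,RSC,904.83,172.07,15
auc,II,plPFC,V1/V2,2963.15,972.68,15
auc,II,plPFC,PtA,2698.31,997.09,15
auc,II,ilPFC,ACC,393.51,55.72,15
auc,II,ilPFC,plPFC,367.92,66.75,15
auc,II,ilPFC,ilPFC,1521.39,379.03,15
auc,II,ilPFC,OFC,646.72,141.09,15
auc,II,ilPFC,RSC,3024.88,900.08,15
auc,II,ilPFC,V1/V2,974.24,205.79,15
auc,II,ilPFC,PtA,1208.80,261.53,15
auc,II,OFC,ACC,645.47,158.26,15
auc,II,OFC,plPFC,496.05,103.38,15
auc,II,OFC,ilPFC,590.06,118.20,15
auc,II,OFC,OFC,576.29,143.41,15
auc,II,OFC,RSC,1006.56,288.62,15
auc,II,OFC,V1/V2,634.90,218.70,15
auc,II,OFC,PtA,495.16,158.10,15
auc,II,aINS,ACC,137.10,14.48,15
auc,II,aINS,plPFC,114.51,23.34,15
auc,II,aINS,ilPFC,196.16,21.01,15
auc,II,aINS,OFC,222.86,21.19,15
auc,II,aINS,RSC,257.16,44.34,15
auc,II,aINS,V1/V2,150.73,18.56,15
auc,II,aINS,PtA,273.46,93.64,15
aps,I,ACC,ACC,0.20,0.09,15
aps,I,ACC,plPFC,0.11,0.06,15
aps,I,ACC,ilPFC,0.03,0.01,15
aps,I,ACC,OFC,0.00,0.00,15
aps,I,ACC,RSC,0.11,0.05,15
aps,I,ACC,V1/V2,0.14,0.08,15
aps,I,ACC,PtA,0.19,0.10,15
aps,I,plPFC,ACC,0.11,0.07,15
aps,I,plPFC,plPFC,0.10,0.05,15
aps,I,plPFC,ilPFC,0.00,0.00,15
aps,I,plPFC,OFC,0.04,0.02,15
aps,I,plPFC,RSC,0.00,0.00,15
aps,I,plPFC,V1/V2,0.36,0.12,15
aps,I,plPFC,PtA,0.40,0.15,15
aps,I,ilPFC,ACC,0.00,0.00,15
aps,I,ilPFC,plPFC,0.00,0.00,15
aps,I,ilPFC,ilPFC,0.06,0.03,15
aps,I,ilPFC,OFC,0.02,0.01,15
aps,I,ilPFC,RSC,0.10,0.04,15
aps,I,ilPFC,V1/V2,0.01,0.01,15
aps,I,ilPFC,PtA,0.01,0.01,15
aps,I,OFC,ACC,0.05,0.03,15
aps,I,OFC,plPFC,0.00,0.00,15
aps,I,OFC,ilPFC,0.00,0.00,15
aps,I,OFC,OFC,0.00,0.00,15
aps,I,OFC,RSC,0.01,0.00,15
aps,I,OFC,V1/V2,0.00,0.00,15
aps,I,OFC,PtA,0.00,0.00,15
aps,I,aINS,ACC,0.00,0.00,15
aps,I,aINS,plPFC,0.00,0.00,15
aps,I,aINS,ilPFC,0.00,0.00,15
aps,I,aINS,OFC,0.00,0.00,15
aps,I,aINS,RSC,0.00,0.00,15
aps,I,aINS,V1/V2,0.00,0.00,15
aps,I,aINS,PtA,0.00,0.00,15
aps,II,ACC,ACC,0.55,0.21,15
aps,II,ACC,plPFC,0.55,0.23,15
aps,II,ACC,ilPFC,0.52,0.18,15
aps,II,ACC,OFC,0.14,0.09,15
aps,II,ACC,RSC,0.13,0.07,15
aps,II,ACC,V1/V2,0.46,0.18,15
aps,II,ACC,PtA,0.48,0.22,15
aps,II,plPFC,ACC,0.26,0.12,15
aps,II,plPFC,plPFC,0.30,0.14,15
aps,II,plPFC,ilPFC,0.00,0.00,15
aps,II,plPFC,OFC,0.05,0.03,15
aps,II,plPFC,RSC,0.02,0.01,15
aps,II,plPFC,V1/V2,1.04,0.36,15
aps,II,plPFC,PtA,0.70,0.26,15
aps,II,ilPFC,ACC,0.00,0.00,15
aps,II,ilPFC,plPFC,0.01,0.00,15
aps,II,ilPFC,ilPFC,0.32,0.11,15
aps,II,ilPFC,OFC,0.09,0.03,15
aps,II,ilPFC,RSC,0.78,0.38,15
aps,II,ilPFC,V1/V2,0.07,0.03,15
aps,II,ilPFC,PtA,0.09,0.04,15
aps,II,OFC,ACC,0.01,0.01,15
aps,II,OFC,plPFC,0.00,0.00,15
aps,II,OFC,ilPFC,0.00,0.00,15
aps,II,OFC,OFC,0.02,0.01,15
aps,II,OFC,RSC,0.11,0.06,15
aps,II,OFC,V1/V2,0.01,0.01,15
aps,II,OFC,PtA,0.02,0.01,15
aps,II,aINS,ACC,0.00,0.00,15
aps,II,aINS,plPFC,0.00,0.00,15
aps,II,aINS,ilPFC,0.00,0.00,15
aps,II,aINS,OFC,0.00,0.00,15
aps,II,aINS,RSC,0.00,0.00,15
aps,II,aINS,V1/V2,0.00,0.00,15
aps,II,aINS,PtA,0.00,0.00,15
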