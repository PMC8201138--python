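isomer,common_name,method,conformer,phi1_deg,phi1_label,phi2_deg,phi2_label,dG_kcal,population_pct
9E11E13E,beta-eleostearic acid,B3LYP,A,120.26,S,118.59,S,0.36,33.41
9E11E13E,beta-eleostearic acid,B3LYP,B,120.11,S,-119.97,S',0.00,61.35
9E11E13E,beta-eleostearic acid,B3LYP,C,-0.78,Syn,-0.03,Syn,3.00,0.39
9E11E13E,beta-eleostearic acid,B3LYP,D,-117.53,S',-0.83,Syn,1.89,2.53
9E11E13E,beta-eleostearic acid,B3LYP,E,-0.75,Syn,-118.55,S',1.94,2.32
9E11E13E,beta-eleostearic acid,APFD,A,119.21,S,117.99,S,0.16,38.68
9E11E13E,beta-eleostearic acid,APFD,B,118.73,S,-118.59,S',0.00,50.67
9E11E13E,beta-eleostearic acid,APFD,C,-0.59,Syn,-0.11,Syn,2.13,1.39
9E11E13E,beta-eleostearic acid,APFD,D,-116.94,S',-0.62,Syn,1.38,4.94
9E11E13E,beta-eleostearic acid,APFD,E,-0.58,Syn,-117.27,S',1.46,4.31
9Z11E13E,alpha-eleostearic acid,B3LYP,A,116.67,S,119.18,S,0.03,25.07
9Z11E13E,alpha-eleostearic acid,B3LYP,B,-118.92,S',-119.37,S',0.15,20.48
9Z11E13E,alpha-eleostearic acid,B3LYP,C,116.88,S,-119.16,S',0.02,25.50
9Z11E13E,alpha-eleostearic acid,B3LYP,D,-118.88,S',119.28,S,0.00,26.38
9Z11E13E,alpha-eleostearic acid,B3LYP,E,-119.43,S',-0.76,Syn,1.38,2.57
9Z11E13E,alpha-eleostearic acid,APFD,A,111.25,S,117.87,S,0.00,36.53
9Z11E13E,alpha-eleostearic acid,APFD,B,-114.31,S',-117.53,S',0.48,16.25
9Z11E13E,alpha-eleostearic acid,APFD,C,112.96,S,-117.54,S',0.18,26.96
9Z11E13E,alpha-eleostearic acid,APFD,D,-113.83,S',118.32,S,0.47,16.52
9Z11E13E,alpha-eleostearic acid,APFD,E,-113.80,S',-0.22,Syn,1.35,3.74
9Z11E13Z,punicic acid,B3LYP,A,117.46,S,119.33,S,0.00,38.54
9Z11E13Z,punicic acid,B3LYP,B,117.76,S,-118.63,S',0.08,33.67
9Z11E13Z,punicic acid,B3LYP,C,-119.22,S',119.55,S,0.27,24.43
9Z11E13Z,punicic acid,B3LYP,D,1.52,,-121.09,S',3.83,1.51
9Z11E13Z,punicic acid,B3LYP,E,117.81,S,2.02,Syn,3.63,1.85
9Z11E13Z,punicic acid,APFD,A,113.45,S,114.70,S,0.00,44.84
9Z11E13Z,punicic acid,APFD,B,112.18,S,-112.33,S',0.31,26.57
9Z11E13Z,punicic acid,APFD,C,-113.43,S',113.54,S,0.27,28.43
9Z11E13Z,punicic acid,APFD,D,5.34,,-110.17,S',3.77,0.08
9Z11E13Z,punicic acid,APFD,E,111.01,S,4.55,Syn,3.78,0.08
10E12E14Z,hexadecatrienyl acetate,B3LYP,A,120.04,S,,,0.28,25.59
10E12E14Z,hexadecatrienyl acetate,B3LYP,B,-119.39,S',,,0.00,41.05
10E12E14Z,hexadecatrienyl acetate,B3LYP,C,120.03,S,,,0.20,29.29
10E12E14Z,hexadecatrienyl acetate,B3LYP,D,1.56,Syn,,,1.37,4.07
10E12E14Z,hexadecatrienyl acetate,APFD,A,118.73,S,,,0.08,28.88
10E12E14Z,hexadecatrienyl acetate,APFD,B,-118.73,S',,,0.03,31.42
10E12E14Z,hexadecatrienyl acetate,APFD,C,118.73,S,,,0.00,33.05
10E12E14Z,hexadecatrienyl acetate,APFD,D,1.16,Syn,,,0.95,6.65
10E12Z14Z,hexadecatrienyl acetate,B3LYP,A,119.67,S,,,0.44,22.44
10E12Z14Z,hexadecatrienyl acetate,B3LYP,B,-119.64,S',,,0.00,47.15
10E12Z14Z,hexadecatrienyl acetate,B3LYP,C,119.56,S,,,0.35,26.12
10E12Z14Z,hexadecatrienyl acetate,B3LYP,D,1.22,Syn,,,1.42,4.29
10E12Z14Z,hexadecatrienyl acetate,APFD,A,118.45,S,,,0.20,26.06
10E12Z14Z,hexadecatrienyl acetate,APFD,B,-118.86,S',,,0.00,36.52
10E12Z14Z,hexadecatrienyl acetate,APFD,C,118.28,S,,,0.12,29.82
10E12Z14Z,hexadecatrienyl acetate,APFD,D,0.87,Syn,,,0.93,7.60
10Z12Z14E,hexadecatrienyl acetate,B3LYP,A,119.01,S,,,0.00,30.52
10Z12Z14E,hexadecatrienyl acetate,B3LYP,B,-119.51,S',,,0.51,12.91
10Z12Z14E,hexadecatrienyl acetate,B3LYP,C,118.80,S,,,0.00,30.52
10Z12Z14E,hexadecatrienyl acetate,B3LYP,D,-119.50,S',,,0.48,13.57
10Z12Z14E,hexadecatrienyl acetate,APFD,A,112.30,S,,,0.04,20.48
10Z12Z14E,hexadecatrienyl acetate,APFD,B,-113.47,S',,,0.10,18.51
10Z12Z14E,hexadecatrienyl acetate,APFD,C,112.24,S,,,0.00,21.92
10Z12Z14E,hexadecatrienyl acetate,APFD,D,-113.16,S',,,0.02,21.19
10Z12E14E,hexadecatrienyl acetate,B3LYP,A,119.05,S,,,0.00,31.98
10Z12E14E,hexadecatrienyl acetate,B3LYP,B,-121.15,S',,,0.54,12.85
10Z12E14E,hexadecatrienyl acetate,B3LYP,C,118.73,S,,,0.04,29.89
10Z12E14E,hexadecatrienyl acetate,B3LYP,D,-121.06,S',,,0.56,12.43
10Z12E14E,hexadecatrienyl acetate,APFD,A,113.03,S,,,0.00,33.79
10Z12E14E,hexadecatrienyl acetate,APFD,B,-116.62,S',,,0.63,11.67
10Z12E14E,hexadecatrienyl acetate,APFD,C,113.00,S,,,0.04,31.59
10Z12E14E,hexadecatrienyl acetate,APFD,D,-116.57,S',,,0.65,11.28
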