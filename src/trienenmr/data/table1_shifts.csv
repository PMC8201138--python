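molecule_id,solvent,site,delta_exp_ppm,source
hexatriene_Z,CHCl3,H1a,5.15,1H/COSY 270 MHz
hexatriene_Z,CHCl3,H1b,5.24,1H/COSY 270 MHz
hexatriene_Z,CHCl3,H2,6.8,1H/COSY 270 MHz
hexatriene_Z,CHCl3,H3,6.0,1H/COSY 270 MHz
hexatriene_Z,CHCl3,H4,6.0,1H/COSY 270 MHz
hexatriene_Z,CHCl3,H5,6.8,1H/COSY 270 MHz
hexatriene_Z,CHCl3,H6a,5.15,1H/COSY 270 MHz
hexatriene_Z,CHCl3,H6b,5.24,1H/COSY 270 MHz
hexatriene_E,CHCl3,H1a,5.1,1H/COSY 270 MHz
hexatriene_E,CHCl3,H1b,5.23,1H/COSY 270 MHz
hexatriene_E,CHCl3,H2,6.36,1H/COSY 270 MHz
hexatriene_E,CHCl3,H3,6.22,1H/COSY 270 MHz
hexatriene_E,CHCl3,H4,6.22,1H/COSY 270 MHz
hexatriene_E,CHCl3,H5,6.36,1H/COSY 270 MHz
hexatriene_E,CHCl3,H6a,5.1,1H/COSY 270 MHz
hexatriene_E,CHCl3,H6b,5.23,1H/COSY 270 MHz
hexatriene_Z_ccl4,CCl4,H1a,5.09,1H 100 MHz
hexatriene_Z_ccl4,CCl4,H1b,5.17,1H 100 MHz
hexatriene_Z_ccl4,CCl4,H2,6.74,1H 100 MHz
hexatriene_Z_ccl4,CCl4,H3,5.93,1H 100 MHz
hexatriene_Z_ccl4,CCl4,H4,5.93,1H 100 MHz
hexatriene_Z_ccl4,CCl4,H5,6.74,1H 100 MHz
hexatriene_Z_ccl4,CCl4,H6a,5.09,1H 100 MHz
hexatriene_Z_ccl4,CCl4,H6b,5.17,1H 100 MHz
hexatriene_E_ccl4,CCl4,H1a,5.05,1H 100 MHz
hexatriene_E_ccl4,CCl4,H1b,5.18,1H 100 MHz
hexatriene_E_ccl4,CCl4,H2,6.3,1H 100 MHz
hexatriene_E_ccl4,CCl4,H3,6.16,1H 100 MHz
hexatriene_E_ccl4,CCl4,H4,6.16,1H 100 MHz
hexatriene_E_ccl4,CCl4,H5,6.3,1H 100 MHz
hexatriene_E_ccl4,CCl4,H6a,5.05,1H 100 MHz
hexatriene_E_ccl4,CCl4,H6b,5.18,1H 100 MHz
octatriene_EZE,CHCl3,H1,1.8,1H 300 MHz
octatriene_EZE,CHCl3,H2,5.7,1H 300 MHz
octatriene_EZE,CHCl3,H3,5.83,1H 300 MHz
octatriene_EZE,CHCl3,H4,6.5,1H 300 MHz
octatriene_EZE,CHCl3,H5,6.5,1H 300 MHz
octatriene_EZE,CHCl3,H6,5.83,1H 300 MHz
octatriene_EZE,CHCl3,H7,5.7,1H 300 MHz
octatriene_EZE,CHCl3,H8,1.8,1H 300 MHz
octatriene_EEE,CCl4,H1,1.84,1H 100 MHz
octatriene_EEE,CCl4,H2,5.69,1H 100 MHz
octatriene_EEE,CCl4,H3,6.12,1H 100 MHz
octatriene_EEE,CCl4,H4,6.10,1H 100 MHz
octatriene_EEE,CCl4,H5,6.10,1H 100 MHz
octatriene_EEE,CCl4,H6,6.12,1H 100 MHz
octatriene_EEE,CCl4,H7,5.69,1H 100 MHz
octatriene_EEE,CCl4,H8,1.84,1H 100 MHz
acetate_10E12E14Z,CHCl3,H9,2.09,1H/13C/COSY 270 MHz
acetate_10E12E14Z,CHCl3,H10,5.70,1H/13C/COSY 270 MHz
acetate_10E12E14Z,CHCl3,H11,6.10,1H/13C/COSY 270 MHz
acetate_10E12E14Z,CHCl3,H12,6.18,1H/13C/COSY 270 MHz
acetate_10E12E14Z,CHCl3,H13,6.41,1H/13C/COSY 270 MHz
acetate_10E12E14Z,CHCl3,H14,6.02,1H/13C/COSY 270 MHz
acetate_10E12E14Z,CHCl3,H15,5.47,1H/13C/COSY 270 MHz
acetate_10E12E14Z,CHCl3,H16,1.76,1H/13C/COSY 270 MHz
acetate_10E12Z14Z,CHCl3,H9,2.12,1H/13C/COSY 270 MHz
acetate_10E12Z14Z,CHCl3,H10,5.74,1H/13C/COSY 270 MHz
acetate_10E12Z14Z,CHCl3,H11,6.50,1H/13C/COSY 270 MHz
acetate_10E12Z14Z,CHCl3,H12,5.98,1H/13C/COSY 270 MHz
acetate_10E12Z14Z,CHCl3,H13,6.16,1H/13C/COSY 270 MHz
acetate_10E12Z14Z,CHCl3,H14,6.46,1H/13C/COSY 270 MHz
acetate_10E12Z14Z,CHCl3,H15,5.56,1H/13C/COSY 270 MHz
acetate_10E12Z14Z,CHCl3,H16,1.77,1H/13C/COSY 270 MHz
acetate_10Z12Z14E,CHCl3,H9,2.18,1H/13C/COSY 270 MHz
acetate_10Z12Z14E,CHCl3,H10,5.48,1H/13C/COSY 270 MHz
acetate_10Z12Z14E,CHCl3,H11,6.43,1H/13C/COSY 270 MHz
acetate_10Z12Z14E,CHCl3,H12,6.13,1H/13C/COSY 270 MHz
acetate_10Z12Z14E,CHCl3,H13,5.96,1H/13C/COSY 270 MHz
acetate_10Z12Z14E,CHCl3,H14,6.52,1H/13C/COSY 270 MHz
acetate_10Z12Z14E,CHCl3,H15,5.75,1H/13C/COSY 270 MHz
acetate_10Z12Z14E,CHCl3,H16,1.80,1H/13C/COSY 270 MHz
acetate_10Z12E14E,CHCl3,H9,2.17,1H/13C/COSY 270 MHz
acetate_10Z12E14E,CHCl3,H10,5.40,1H/13C/COSY 270 MHz
acetate_10Z12E14E,CHCl3,H11,5.98,1H/13C/COSY 270 MHz
acetate_10Z12E14E,CHCl3,H12,6.37,1H/13C/COSY 270 MHz
acetate_10Z12E14E,CHCl3,H13,6.16,1H/13C/COSY 270 MHz
acetate_10Z12E14E,CHCl3,H14,6.07,1H/13C/COSY 270 MHz
acetate_10Z12E14E,CHCl3,H15,5.70,1H/13C/COSY 270 MHz
acetate_10Z12E14E,CHCl3,H16,1.77,1H/13C/COSY 270 MHz
beta_eleostearic,CHCl3,H11,6.10,1H/13C/COSY 400 MHz
beta_eleostearic,CHCl3,H12,6.10,1H/13C/COSY 400 MHz
beta_eleostearic,CHCl3,H10,6.04,1H/13C/COSY 400 MHz
beta_eleostearic,CHCl3,H13,6.04,1H/13C/COSY 400 MHz
beta_eleostearic,CHCl3,H9,5.66,1H/13C/COSY 400 MHz
beta_eleostearic,CHCl3,H14,5.66,1H/13C/COSY 400 MHz
beta_eleostearic,CHCl3,H2,2.37,1H/13C/COSY 400 MHz
beta_eleostearic,CHCl3,H8,2.10,1H/13C/COSY 400 MHz
beta_eleostearic,CHCl3,H15,2.10,1H/13C/COSY 400 MHz
beta_eleostearic,CHCl3,H3,1.65,1H/13C/COSY 400 MHz
beta_eleostearic,CHCl3,H4,1.39,1H/13C/COSY 400 MHz
beta_eleostearic,CHCl3,H5,1.39,1H/13C/COSY 400 MHz
beta_eleostearic,CHCl3,H6,1.39,1H/13C/COSY 400 MHz
beta_eleostearic,CHCl3,H7,1.39,1H/13C/COSY 400 MHz
beta_eleostearic,CHCl3,H16,1.33,1H/13C/COSY 400 MHz
beta_eleostearic,CHCl3,H17,1.33,1H/13C/COSY 400 MHz
beta_eleostearic,CHCl3,H18,0.91,1H/13C/COSY 400 MHz
alpha_eleostearic,CHCl3,H11,6.19,1H/13C/COSY 400 MHz
alpha_eleostearic,CHCl3,H12,6.40,1H/13C/COSY 400 MHz
alpha_eleostearic,CHCl3,H10,6.01,1H/13C/COSY 400 MHz
alpha_eleostearic,CHCl3,H13,6.12,1H/13C/COSY 400 MHz
alpha_eleostearic,CHCl3,H9,5.4,1H/13C/COSY 400 MHz
alpha_eleostearic,CHCl3,H14,5.74,1H/13C/COSY 400 MHz
alpha_eleostearic,CHCl3,H2,2.40,1H/13C/COSY 400 MHz
alpha_eleostearic,CHCl3,H8,2.20,1H/13C/COSY 400 MHz
alpha_eleostearic,CHCl3,H15,2.20,1H/13C/COSY 400 MHz
alpha_eleostearic,CHCl3,H3,1.64,1H/13C/COSY 400 MHz
alpha_eleostearic,CHCl3,H4,1.41,1H/13C/COSY 400 MHz
alpha_eleostearic,CHCl3,H5,1.41,1H/13C/COSY 400 MHz
alpha_eleostearic,CHCl3,H6,1.41,1H/13C/COSY 400 MHz
alpha_eleostearic,CHCl3,H7,1.41,1H/13C/COSY 400 MHz
alpha_eleostearic,CHCl3,H16,1.33,1H/13C/COSY 400 MHz
alpha_eleostearic,CHCl3,H17,1.33,1H/13C/COSY 400 MHz
alpha_eleostearic,CHCl3,H18,0.97,1H/13C/COSY 400 MHz
punicic,CHCl3,H11,6.48,1H/13C/COSY 400 MHz
punicic,CHCl3,H12,6.48,1H/13C/COSY 400 MHz
punicic,CHCl3,H10,6.08,1H/13C/COSY 400 MHz
punicic,CHCl3,H13,6.08,1H/13C/COSY 400 MHz
punicic,CHCl3,H9,5.46,1H/13C/COSY 400 MHz
punicic,CHCl3,H14,5.46,1H/13C/COSY 400 MHz
punicic,CHCl3,H2,2.37,1H/13C/COSY 400 MHz
punicic,CHCl3,H8,2.22,1H/13C/COSY 400 MHz
punicic,CHCl3,H15,2.22,1H/13C/COSY 400 MHz
punicic,CHCl3,H3,1.65,1H/13C/COSY 400 MHz
punicic,CHCl3,H4,1.39,1H/13C/COSY 400 MHz
punicic,CHCl3,H5,1.39,1H/13C/COSY 400 MHz
punicic,CHCl3,H6,1.39,1H/13C/COSY 400 MHz
punicic,CHCl3,H7,1.39,1H/13C/COSY 400 MHz
punicic,CHCl3,H16,1.32,1H/13C/COSY 400 MHz
punicic,CHCl3,H17,1.32,1H/13C/COSY 400 MHz
punicic,CHCl3,H18,0.94,1H/13C/COSY 400 MHz
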