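# Human tissue composition for mechanistic partition-coefficient methods.
# Fractional volumes of extracellular water (f_ew), intracellular water
# (f_iw), neutral lipid (f_nl), neutral phospholipid (f_np), and the
# tissue-interstitial-to-plasma albumin concentration ratio (alb_ratio).
# Values are standard Rodgers-Rowland-family human compositions
# (approximate, rounded); the 'plasma' row carries plasma water and lipid
# fractions. uterus/placenta/rest/fetal_tissue rows are lumped-tissue
# entries assembled from the muscle/spleen compositions. Version 1.
tissue,f_ew,f_iw,f_nl,f_np,alb_ratio
adipose,0.135,0.017,0.8530,0.0016,0.049
brain,0.162,0.620,0.0392,0.0533,0.048
heart,0.320,0.456,0.0115,0.0166,0.157
kidney,0.273,0.483,0.0207,0.0162,0.130
liver,0.161,0.573,0.0348,0.0252,0.086
lung,0.336,0.446,0.0030,0.0090,0.212
muscle,0.118,0.630,0.0238,0.0072,0.064
skin,0.382,0.291,0.0284,0.0111,0.277
spleen,0.207,0.579,0.0201,0.0198,0.097
uterus,0.180,0.600,0.0200,0.0100,0.080
placenta,0.300,0.450,0.0080,0.0120,0.150
rest,0.250,0.450,0.0500,0.0150,0.100
fetal_tissue,0.220,0.560,0.0200,0.0100,0.080
plasma,0.945,0.000,0.0023,0.0013,1.000
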