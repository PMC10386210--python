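drug,ror,ci_low,ci_high,p_value
Alclometasone dipropionate,2.10,0.13,33.65,1.000
Amcinonide,43.99,2.65,731.68,1.000
Beclometasone dipropionate,13.90,7.07,27.33,<0.001
Betamethasone,3.53,2.02,6.15,<0.001
Betamethasone butyrate propionate,4.12,2.10,8.08,0.001
Betamethasone dipropionate,36.99,14.52,94.28,<0.001
Betamethasone sodium phosphate,12.41,8.95,17.22,<0.001
Betamethasone valerate,7.41,2.93,18.73,0.004
Budesonide,4.63,1.84,11.70,0.017
Ciclesonide,1.40,0.09,22.39,1.000
Clobetasol propionate,5.89,3.30,10.52,<0.001
Clobetasone butyrate,11.97,4.18,34.29,0.003
Cortisone acetate,12.32,0.76,199.16,1.000
Deprodone propionate,9.56,0.59,154.25,1.000
Dexamethasone,0.67,0.41,1.09,0.085
Dexamethasone cipecilate,50.77,9.98,258.32,0.030
Dexamethasone dipropionate,12.40,3.57,43.08,0.018
Dexamethasone palmitate,3.64,0.73,18.08,0.338
Dexamethasone sodium metasulfobenzoate,98.96,33.57,291.78,<0.001
Dexamethasone sodium phosphate,1.03,0.67,1.60,0.910
Dexamethasone valerate,25.74,8.95,74.07,<0.001
Diflorasone diacetate,10.71,3.74,30.66,0.005
Diflucortolone valerate,21.37,11.61,39.33,<0.001
Difluprednate,6.55,3.57,12.01,<0.001
Fludrocortisone acetate,2.04,0.13,32.67,1.000
Fludroxycortide,4.49,0.28,72.07,1.000
Fluocinolone acetonide,9.93,0.62,160.27,1.000
Fluocinonide,2.71,0.17,43.38,1.000
Fluorometholone,27.09,18.00,40.79,<0.001
Fluticasone furoate,15.03,7.32,30.88,<0.001
Fluticasone propionate,11.95,7.64,18.68,<0.001
Hydrocortisone acetate,9.95,5.57,17.79,<0.001
Hydrocortisone probutate,49.06,13.92,172.9,0.001
Hydrocortisone sodium phosphate,3.10,1.09,8.86,0.106
Hydrocortisone sodium succinate,0.84,0.36,1.93,0.696
Methylprednisolone,2.12,1.34,3.35,0.006
Methylprednisolone acetate,1.72,0.11,27.61,1.000
Methylprednisolone sodium succinate,2.80,1.97,3.98,<0.001
Mometasone furoate,8.74,2.52,30.32,0.034
Mometasone furoate monohydrate,9.98,3.49,28.56,0.006
Prednisolone,1.93,1.62,2.29,<0.001
Prednisolone acetate,1.46,0.63,3.38,0.435
Prednisolone sodium phosphate,4.17,0.26,66.97,1.000
Prednisolone sodium succinate,1.15,0.40,3.29,1.000
Prednisolone valeroacetate,22.78,12.00,43.27,<0.001
Triamcinolone,11.64,2.33,58.03,0.122
Triamcinolone acetonide,57.41,46.63,70.67,<0.001
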