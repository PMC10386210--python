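# The 47 corticosteroids in clinical use in Japan as prescription drugs
# (combination products and discontinued products excluded) that appear in
# the JADER 2004-04 .. 2022-06 extract.  One printed-source typo is shipped
# cleaned: "Hydrocortisone Probutat" -> "Hydrocortisone probutate".
name: corticosteroids-japan
drugs:
  - Alclometasone dipropionate
  - Amcinonide
  - Beclometasone dipropionate
  - Betamethasone
  - Betamethasone butyrate propionate
  - Betamethasone dipropionate
  - Betamethasone sodium phosphate
  - Betamethasone valerate
  - Budesonide
  - Ciclesonide
  - Clobetasol propionate
  - Clobetasone butyrate
  - Cortisone acetate
  - Deprodone propionate
  - Dexamethasone
  - Dexamethasone cipecilate
  - Dexamethasone dipropionate
  - Dexamethasone palmitate
  - Dexamethasone sodium metasulfobenzoate
  - Dexamethasone sodium phosphate
  - Dexamethasone valerate
  - Diflorasone diacetate
  - Diflucortolone valerate
  - Difluprednate
  - Fludrocortisone acetate
  - Fludroxycortide
  - Fluocinolone acetonide
  - Fluocinonide
  - Fluorometholone
  - Fluticasone furoate
  - Fluticasone propionate
  - Hydrocortisone acetate
  - Hydrocortisone probutate
  - Hydrocortisone sodium phosphate
  - Hydrocortisone sodium succinate
  - Methylprednisolone
  - Methylprednisolone acetate
  - Methylprednisolone sodium succinate
  - Mometasone furoate
  - Mometasone furoate monohydrate
  - Prednisolone
  - Prednisolone acetate
  - Prednisolone sodium phosphate
  - Prednisolone sodium succinate
  - Prednisolone valeroacetate
  - Triamcinolone
  - Triamcinolone acetonide
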