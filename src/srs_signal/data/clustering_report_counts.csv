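drug,n_reports
Clobetasol propionate,3023
Diflucortolone valerate,768
Difluprednate,2485
Dexamethasone,37816
Dexamethasone sodium phosphate,30523
Triamcinolone acetonide,2693
Hydrocortisone butyrate,1794
Fluorometholone,1366
Fluticasone propionate,2543
Prednisolone,107943
Betamethasone,5483
Betamethasone sodium phosphate,4604
Methylprednisolone sodium succinate,17429
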