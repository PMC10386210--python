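pt_name,n_reports
Acute myopia,0
Angle-closure glaucoma,507
Aphakic glaucoma,0
Borderline glaucoma,0
Diabetic glaucoma,0
Exfoliation glaucoma,1
Fundoscopy abnormal,21
Glaucoma,1790
Glaucoma drug therapy,0
Glaucomatocyclitic crises,16
Glaucomatous optic disc atrophy,1
Gonioscopy abnormal,0
Halo vision,0
Intraocular pressure fluctuation,2
Intraocular pressure increased,838
Intraocular pressure test abnormal,1
Loss of visual contrast sensitivity,1
Malignant glaucoma,4
Normal tension glaucoma,52
Ocular hypertension,272
Open-angle glaucoma,41
Optic discs blurred,1
Optic nerve cup/disc ratio increased,0
Optic nerve cupping,40
Phacolytic glaucoma,0
Pigmentary glaucoma,0
Pseudophakic glaucoma,0
Pupillary light reflex tests abnormal,7
Slit-lamp tests abnormal,0
Uveitic glaucoma,1
Uveitis-glaucoma-hyphaema syndrome,0
Visual field tests abnormal,15
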