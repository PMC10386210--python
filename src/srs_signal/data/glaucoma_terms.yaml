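# Glaucoma event definition: 32 MedDRA/J v25.0 preferred terms, the narrow
# scope of the glaucoma standardized MedDRA query minus congenital,
# traumatic, postoperative and surgical terms.  Two garbled printed
# spellings are shipped cleaned, with the originals retained as synonyms.
name: glaucoma
provenance: "SMQ narrow scope, MedDRA/J version 25.0, excluding congenital/traumatic/postoperative/surgical terms"
pts:
  - Acute myopia
  - Angle-closure glaucoma
  - Aphakic glaucoma
  - Borderline glaucoma
  - Diabetic glaucoma
  - Exfoliation glaucoma
  - Fundoscopy abnormal
  - Glaucoma
  - Glaucoma drug therapy
  - Glaucomatocyclitic crises
  - Glaucomatous optic disc atrophy
  - Gonioscopy abnormal
  - Halo vision
  - Intraocular pressure fluctuation
  - Intraocular pressure increased
  - Intraocular pressure test abnormal
  - Loss of visual contrast sensitivity
  - Malignant glaucoma
  - Normal tension glaucoma
  - Ocular hypertension
  - Open-angle glaucoma
  - Optic discs blurred
  - Optic nerve cup/disc ratio increased
  - Optic nerve cupping
  - Phacolytic glaucoma
  - Pigmentary glaucoma
  - Pseudophakic glaucoma
  - Pupillary light reflex tests abnormal
  - Slit-lamp tests abnormal
  - Uveitic glaucoma
  - Uveitis-glaucoma-hyphaema syndrome
  - Visual field tests abnormal
synonyms:
  "The optical nerve cup/disc ratio increased": "Optic nerve cup/disc ratio increased"
  "The visualVisual field tests abnormal": "Visual field tests abnormal"
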