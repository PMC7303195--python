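tissue	gene	rsid	effect_size
Adipose Subcutaneous	ADH1A	rs1693457	0.638
Adipose Subcutaneous	ADH1A	rs1789882	0.638
Adipose Subcutaneous	ADH1A	rs1789891	-0.342
Adipose Subcutaneous	ADH1A	rs2066702	-0.696
Adipose Subcutaneous	ADH1A	rs904092	0.634
Adipose Subcutaneous	ADH1B	rs1826907	-0.174
Adipose Subcutaneous	ADH1C	rs12639833	0.252
Adipose Subcutaneous	ADH1C	rs1614972	0.255
Adipose Subcutaneous	ADH1C	rs1789891	-0.321
Adipose Subcutaneous	ADH1C	rs1789924	-0.459
Adipose Subcutaneous	ADH1C	rs2173201	0.252
Adipose Subcutaneous	ADH1C	rs2241894	0.256
Adipose Subcutaneous	ADH4	rs1789924	-0.26
Adipose Visceral Omentum	ADH1C	rs1789924	-0.409
Adrenal Gland	ADH1A	rs1693457	0.539
Adrenal Gland	ADH1A	rs1789882	0.54
Adrenal Gland	ADH1A	rs904092	0.54
Artery Aorta	ADH1A	rs1693457	0.691
Artery Aorta	ADH1A	rs1789882	0.691
Artery Aorta	ADH1A	rs1789891	-0.484
Artery Aorta	ADH1A	rs904092	0.692
Artery Aorta	ADH1B	rs1826907	-0.296
Artery Tibial	ADH1A	rs1693457	0.479
Artery Tibial	ADH1A	rs1789882	0.49
Artery Tibial	ADH1A	rs904092	0.489
Artery Tibial	ADH1B	rs1826907	-0.298
Artery Tibial	ADH1C	rs1789891	-0.279
Artery Tibial	ADH1C	rs1789924	-0.26
Brain Caudate basal ganglia	ADH1C	rs12639833	0.632
Brain Caudate basal ganglia	ADH1C	rs2173201	0.634
Brain Caudate basal ganglia	ADH1C	rs2241894	0.623
Breast Mammary Tissue	ADH1A	rs1693457	0.491
Breast Mammary Tissue	ADH1A	rs1789882	0.491
Breast Mammary Tissue	ADH1A	rs904092	0.491
Breast Mammary Tissue	ADH1C	rs1789924	-0.385
Cells Transformed fibroblasts	ADH1A	rs1693457	0.336
Cells Transformed fibroblasts	ADH1A	rs1789882	0.336
Cells Transformed fibroblasts	ADH1A	rs1826907	-0.272
Cells Transformed fibroblasts	ADH1A	rs904092	0.343
Cells Transformed fibroblasts	ADH1B	rs1826907	-0.166
Cells Transformed fibroblasts	ADH1C	rs1826907	-0.224
Colon Sigmoid	ADH1A	rs1693457	0.636
Colon Sigmoid	ADH1A	rs1789882	0.636
Colon Sigmoid	ADH1A	rs904092	0.636
Colon Sigmoid	ADH1C	rs1789924	-0.383
Colon Transverse	ADH1A	rs1693457	0.447
Colon Transverse	ADH1A	rs1789882	0.433
Esophagus Gastroesophageal Junction	ADH1A	rs1693457	0.424
Esophagus Mucosa	ADH1C	rs12639833	0.371
Esophagus Mucosa	ADH1C	rs1614972	0.284
Esophagus Mucosa	ADH1C	rs1789891	-0.285
Esophagus Mucosa	ADH1C	rs1789924	-0.308
Esophagus Mucosa	ADH1C	rs2173201	0.375
Esophagus Mucosa	ADH1C	rs2241894	0.373
Esophagus Muscularis	ADH1A	rs1693457	0.438
Esophagus Muscularis	ADH1A	rs1789882	0.438
Esophagus Muscularis	ADH1A	rs904092	0.427
Esophagus Muscularis	ADH1C	rs1789924	-0.273
Esophagus Muscularis	ADH4	rs12639833	0.387
Esophagus Muscularis	ADH4	rs2173201	0.404
Esophagus Muscularis	ADH4	rs2241894	0.393
Heart Atrial Appendage	ADH1A	rs1693457	0.577
Heart Atrial Appendage	ADH1A	rs1789882	0.586
Heart Atrial Appendage	ADH1A	rs904092	0.586
Heart Atrial Appendage	ADH1C	rs12639833	0.328
Heart Atrial Appendage	ADH1C	rs1789891	-0.501
Heart Atrial Appendage	ADH1C	rs1789924	-0.508
Heart Atrial Appendage	ADH1C	rs2173201	0.332
Heart Atrial Appendage	ADH1C	rs2241894	0.332
Heart Left Ventricle	ADH1A	rs1693457	0.476
Heart Left Ventricle	ADH1A	rs1789882	0.471
Heart Left Ventricle	ADH1A	rs904092	0.458
Heart Left Ventricle	ADH1C	rs1789924	-0.362
Lung	ADH1A	rs1693457	0.646
Lung	ADH1A	rs1789882	0.648
Lung	ADH1A	rs904092	0.648
Lung	ADH1C	rs12639833	0.336
Lung	ADH1C	rs1614972	0.289
Lung	ADH1C	rs1789924	-0.266
Lung	ADH1C	rs2241894	0.337
Lung	ADH1C	rs9307239	0.216
Lung	ADH1C	rs2173201	0.338
Muscle Skeletal	ADH1B	rs1826907	-0.24
Muscle Skeletal	ADH4	rs12639833	0.31
Muscle Skeletal	ADH4	rs1614972	0.256
Muscle Skeletal	ADH4	rs2173201	0.305
Muscle Skeletal	ADH4	rs2241894	0.305
Muscle Skeletal	ADH4	rs9307239	0.237
Nerve Tibial	ADH1A	rs1693457	0.372
Nerve Tibial	ADH1A	rs1789882	0.372
Nerve Tibial	ADH1A	rs904092	0.373
Nerve Tibial	ADH1B	rs1826907	-0.301
Nerve Tibial	ADH1C	rs1789891	-0.297
Nerve Tibial	ADH1C	rs1789924	-0.221
Pancreas	ADH1C	rs12639833	0.53
Pancreas	ADH1C	rs2173201	0.534
Pancreas	ADH1C	rs2241894	0.536
Skin Not Sun Exposed Suprapubic	ADH1A	rs1693457	0.327
Skin Not Sun Exposed Suprapubic	ADH1A	rs1789882	0.342
Skin Not Sun Exposed Suprapubic	ADH1A	rs904092	0.344
Skin Not Sun Exposed Suprapubic	ADH1C	rs1789924	-0.253
Skin Sun Exposed Lower leg	ADH1A	rs1693457	0.461
Skin Sun Exposed Lower leg	ADH1A	rs1789882	0.463
Skin Sun Exposed Lower leg	ADH1A	rs904092	0.457
Skin Sun Exposed Lower leg	ADH1C	rs12639833	0.233
Skin Sun Exposed Lower leg	ADH1C	rs1789924	-0.257
Skin Sun Exposed Lower leg	ADH1C	rs2173201	0.236
Skin Sun Exposed Lower leg	ADH1C	rs2241894	0.239
Small Intestine Terminal Ileum	ADH1A	rs1693457	0.727
Small Intestine Terminal Ileum	ADH1A	rs1789882	0.727
Small Intestine Terminal Ileum	ADH1A	rs904092	0.74
Spleen	ADH1C	rs12639833	0.588
Spleen	ADH1C	rs2173201	0.572
Spleen	ADH1C	rs2241894	0.602
Thyroid	ADH1A	rs1693457	0.441
Thyroid	ADH1A	rs1789882	0.44
Thyroid	ADH1A	rs904092	0.444
Thyroid	ADH1B	rs1826907	-0.217
Thyroid	ADH1C	rs1789924	-0.264
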