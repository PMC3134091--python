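study,treatment,outcome,mean,se,r,n
Barkhuizen2006,placebo,basfi_cfb,2.00,3.00,,
Barkhuizen2006,celecoxib200,basfi_cfb,-9.00,0.50,,
Barkhuizen2006,celecoxib400,basfi_cfb,-11.00,1.00,,
Barkhuizen2006,naproxen1000,basfi_cfb,-16.00,2.00,,
VanDerHeijde2005,placebo,basfi_cfb,-4.00,1.90,,
VanDerHeijde2005,naproxen1000,basfi_cfb,-14.60,1.80,,
VanDerHeijde2005,etoricoxib90,basfi_cfb,-19.40,1.80,,
Dougados2001,placebo,basfi_cfb,1.30,2.03,,
Dougados2001,celecoxib200,basfi_cfb,-11.90,2.46,,
Sieper2008,celecoxib200,basfi_cfb,-8.00,1.62,,
Sieper2008,celecoxib400,basfi_cfb,-9.00,1.23,,
Sieper2008,diclofenac150,basfi_cfb,-9.00,1.45,,
VanDerHeijde2005,placebo,basdai_cfb,-6.40,1.90,,
VanDerHeijde2005,naproxen1000,basdai_cfb,-23.60,1.80,,
VanDerHeijde2005,etoricoxib90,basdai_cfb,-28.60,1.80,,
Sieper2008,celecoxib200,basdai_cfb,-9.90,1.71,,
Sieper2008,celecoxib400,basdai_cfb,-13.20,1.40,,
Sieper2008,diclofenac150,basdai_cfb,-14.80,1.41,,
Barkhuizen2006,placebo,discontinuation,,,59,156
Barkhuizen2006,celecoxib200,discontinuation,,,25,137
Barkhuizen2006,celecoxib400,discontinuation,,,23,161
Barkhuizen2006,naproxen1000,discontinuation,,,17,157
VanDerHeijde2005,placebo,discontinuation,,,44,93
VanDerHeijde2005,naproxen1000,discontinuation,,,20,97
VanDerHeijde2005,etoricoxib90,discontinuation,,,8,100
Dougados2001,placebo,discontinuation,,,31,76
Dougados2001,celecoxib200,discontinuation,,,18,80
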