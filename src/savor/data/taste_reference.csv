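compound,compound_class,taste_attribute,threshold,umami_coefficient,is_essential
Glu,FAA,umami,30,1.0,False
Asp,FAA,umami,100,0.077,False
Ala,FAA,sweet,60,,False
Gly,FAA,sweet,130,,False
Pro,FAA,sweet,300,,False
Ser,FAA,sweet,150,,False
Thr,FAA,sweet,260,,True
Arg,FAA,bitter,50,,False
Lys,FAA,bitter,50,,True
Leu,FAA,bitter,190,,True
Phe,FAA,bitter,90,,True
Val,FAA,bitter,40,,True
Ile,FAA,bitter,90,,True
Tyr,FAA,bitter,,,False
His,FAA,bitter,20,,True
Trp,FAA,bitter,200,,True
Met,FAA,bitter,30,,True
Gln,FAA,tasteless,,,False
Asn,FAA,tasteless,,,False
Cys,FAA,tasteless,,,False
IMP,nucleotide,umami,25,1.0,False
AMP,nucleotide,umami,50,0.18,False
GMP,nucleotide,umami,12.5,2.3,False
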