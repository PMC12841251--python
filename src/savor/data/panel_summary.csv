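compound,group,mean,sd
Glu,CK48,143.25,13.05
Glu,ICE48,137.91,6.66
Glu,LTA48,81.8,3.25
Asp,CK48,25.68,2.58
Asp,ICE48,75.15,4.72
Asp,LTA48,71.03,3.12
Ala,CK48,249.76,20.24
Ala,ICE48,540.15,30.62
Ala,LTA48,328.37,17.31
Gly,CK48,119.01,3.26
Gly,ICE48,137.87,6.1
Gly,LTA48,117.21,5.15
Pro,CK48,79.14,3.9
Pro,ICE48,18.19,3.23
Pro,LTA48,18.08,0.62
Ser,CK48,49.69,9.29
Ser,ICE48,10.76,0.86
Ser,LTA48,8.39,1.12
Thr,CK48,46.48,8.52
Thr,ICE48,12.04,1.96
Thr,LTA48,9.64,1.11
Arg,CK48,426.38,46.84
Arg,ICE48,387.02,49.04
Arg,LTA48,273.57,17.81
Lys,CK48,117.89,5.73
Lys,ICE48,69.67,7.45
Lys,LTA48,97.79,2.71
Leu,CK48,112.07,6.65
Leu,ICE48,19.68,2.57
Leu,LTA48,26.76,3.5
Phe,CK48,105.88,2.46
Phe,ICE48,14.66,2.34
Phe,LTA48,25.87,1.92
Val,CK48,77.46,2.46
Val,ICE48,14.11,2.55
Val,LTA48,19.96,1.45
Ile,CK48,69.63,3.79
Ile,ICE48,9.5,1.28
Ile,LTA48,10.75,1.18
Tyr,CK48,63.24,5.12
Tyr,ICE48,20.18,1.29
Tyr,LTA48,36.27,2.15
His,CK48,47.84,8.14
His,ICE48,11.98,1.58
His,LTA48,16.67,0.46
Trp,CK48,35.16,4.59
Trp,ICE48,12.88,1.87
Trp,LTA48,26.08,2.34
Met,CK48,34.91,3.33
Met,ICE48,7.91,0.47
Met,LTA48,13.66,0.5
Gln,CK48,107.04,8.11
Gln,ICE48,46.74,2.72
Gln,LTA48,32.52,1.61
Asn,CK48,39.61,8.54
Asn,ICE48,3.94,0.33
Asn,LTA48,7.04,0.5
Cys,CK48,7.54,0.37
Cys,ICE48,5.04,0.2
Cys,LTA48,4.85,1.1
IMP,CK48,91.79,6.08
IMP,ICE48,233.12,13.66
IMP,LTA48,106.32,3.13
AMP,CK48,43.22,3.95
AMP,ICE48,53.45,1.97
AMP,LTA48,122.79,5.27
GMP,CK48,9.46,1.62
GMP,ICE48,11.81,1.61
GMP,LTA48,10.24,0.33
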