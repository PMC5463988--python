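# Synthetic stand-in for the mean amino-acid composition of the human
# reference proteome: counts are widely published approximate human-proteome
# residue frequencies (percent) scaled to a representative mean length of 560
# residues.  Not derived from any proteome file shipped with this package.
id,organism,chains,Ala,Arg,Asn,Asp,Cys,Gln,Glu,Gly,His,Ile,Leu,Lys,Met,Phe,Pro,Ser,Thr,Trp,Tyr,Val
human_mean,Homo sapiens (synthetic mean),1,39.2,31.36,20.16,26.32,12.88,26.88,39.76,36.96,14.56,24.08,56.0,31.92,11.76,20.72,35.28,46.48,29.68,6.72,15.12,34.16
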