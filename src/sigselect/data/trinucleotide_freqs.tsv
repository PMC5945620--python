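trinucleotide	genome	exome
ACA	0.03808077	0.03333333
ACC	0.02646291	0.03333333
ACG	0.00661573	0.01666667
ACT	0.03808077	0.03333333
CCA	0.02646291	0.03333333
CCC	0.01838948	0.03333333
CCG	0.00459737	0.01666667
CCT	0.02646291	0.03333333
GCA	0.02646291	0.03333333
GCC	0.01838948	0.03333333
GCG	0.00459737	0.01666667
GCT	0.02646291	0.03333333
TCA	0.03808077	0.03333333
TCC	0.02646291	0.03333333
TCG	0.00661573	0.01666667
TCT	0.03808077	0.03333333
ATA	0.05479915	0.03333333
ATC	0.03808077	0.03333333
ATG	0.03808077	0.03333333
ATT	0.05479915	0.03333333
CTA	0.03808077	0.03333333
CTC	0.02646291	0.03333333
CTG	0.02646291	0.03333333
CTT	0.03808077	0.03333333
GTA	0.03808077	0.03333333
GTC	0.02646291	0.03333333
GTG	0.02646291	0.03333333
GTT	0.03808077	0.03333333
TTA	0.05479915	0.03333333
TTC	0.03808077	0.03333333
TTG	0.03808077	0.03333333
TTT	0.05479915	0.03333333
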