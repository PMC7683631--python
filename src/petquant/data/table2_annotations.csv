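case_id,annotation
2,G13D (c.38G > A) exon 2
5,G12D (c.35G > A) exon 2
6,A146T (c.436G > A) exon 4
7,G12A (c.35G > C) exon 2
8,G12D (c.35G > A) exon 2
9,"Whole gene amplification 12p12.1, FC:2.1"
11,Q61H (c. 183A > C) exon 3
14,G13D (c.38G > A) exon 2
15,G12V (c.35G > T) exon 2
16,G12D (c.35G > A) exon 2
23,G12D (c.35G > A) exon 2
24,G13D (c.38G > A) exon 2
25,G12D (c.35G > A) exon 2
28,"Whole gene amplification 12p12.1, FC: 23.0 (Inv. Panel)"
31,Q61H (c.183A > T) exon 3
32,G13D (c.38G > A) exon 2
35,G12C (c.34 G > T) exon 2
37,"Whole gene amplification 12p12.1, FC: 8.5"
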