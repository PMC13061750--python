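# mitorder gene-name synonym table, version 1
# Maps GenBank annotation dialects onto the 13 canonical mitochondrial
# protein-coding gene labels used throughout the package.
# Matching is case-insensitive and ignores spaces, hyphens and underscores.
# columns: synonym<TAB>canonical
atp6	atp6
atpase6	atp6
atpase_6	atp6
atp_synthase_f0_subunit_6	atp6
atp_synthase_subunit_6	atp6
atp8	atp8
atpase8	atp8
atpase_8	atp8
atp_synthase_f0_subunit_8	atp8
atp_synthase_subunit_8	atp8
cox1	cox1
coi	cox1
co1	cox1
coxi	cox1
cox_1	cox1
cytochrome_c_oxidase_subunit_1	cox1
cytochrome_c_oxidase_subunit_i	cox1
cytochrome_oxidase_subunit_1	cox1
cytochrome_oxidase_subunit_i	cox1
cox2	cox2
coii	cox2
co2	cox2
coxii	cox2
cytochrome_c_oxidase_subunit_2	cox2
cytochrome_c_oxidase_subunit_ii	cox2
cytochrome_oxidase_subunit_2	cox2
cytochrome_oxidase_subunit_ii	cox2
cox3	cox3
coiii	cox3
co3	cox3
coxiii	cox3
cytochrome_c_oxidase_subunit_3	cox3
cytochrome_c_oxidase_subunit_iii	cox3
cytochrome_oxidase_subunit_3	cox3
cytochrome_oxidase_subunit_iii	cox3
cytb	cytb
cob	cytb
cyt_b	cytb
cytochrome_b	cytb
cytochrome_b_apoenzyme	cytb
nad1	nad1
nd1	nad1
nadh1	nad1
nadh_dehydrogenase_subunit_1	nad1
nad2	nad2
nd2	nad2
nadh2	nad2
nadh_dehydrogenase_subunit_2	nad2
nad3	nad3
nd3	nad3
nadh3	nad3
nadh_dehydrogenase_subunit_3	nad3
nad4	nad4
nd4	nad4
nadh4	nad4
nadh_dehydrogenase_subunit_4	nad4
nad4l	nad4l
nd4l	nad4l
nadh4l	nad4l
nadh_dehydrogenase_subunit_4l	nad4l
nad5	nad5
nd5	nad5
nadh5	nad5
nadh_dehydrogenase_subunit_5	nad5
nad6	nad6
nd6	nad6
nadh6	nad6
nadh_dehydrogenase_subunit_6	nad6
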