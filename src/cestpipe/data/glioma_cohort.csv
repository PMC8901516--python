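patient,diagnosis,who_grade,idh_mutation,codeletion_1p19q,tumour_volume_ml,hyperintense_volume_ml,hyperintense_pct
P01,Oligodendroglioma,II,yes,yes,43.7,1.1,2.4
P02,Oligodendroglioma,II,yes,yes,177.6,41.2,23.2
P03,Oligodendroglioma,II,yes,yes,25.1,1.9,7.5
P04,Oligodendroglioma,II,yes,yes,227.1,57.0,25.1
P05,Oligodendroglioma,II,yes,yes,8.7,1.9,21.3
P06,Oligodendroglioma,II,yes,yes,16.9,1.1,6.4
P07,Oligodendroglioma,II,yes,yes,20.8,4.6,22.1
P08,Astrocytoma,II,yes,no,80.0,28.1,35.1
P09,Astrocytoma,III,yes,no,37.5,7.8,20.9
P10,Astrocytoma,III,yes,no,62.6,21.0,33.6
P11,Astrocytoma,III,yes,no,29.5,3.8,13.0
P12,Astrocytoma,III,yes,no,79.7,4.1,5.2
P13,Glioblastoma,IV,no,no,12.8,7.0,54.5
P14,Anaplastic astrocytoma,III,no,no,13.8,1.8,13.4
P15,Glioblastoma,IV,no,no,20.2,1.2,5.8
P16,Glioblastoma,IV,no,unknown,40.5,5.4,13.3
P17,Glioblastoma,IV,no,no,78.6,9.1,11.5
P18,Glioblastoma,IV,no,no,13.5,1.1,8.0
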