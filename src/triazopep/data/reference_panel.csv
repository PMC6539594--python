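id,sequence,subseries,charge,formula_printed,calc_mz_printed,meas_mz_printed,inh,inh_sd,log_ic50,log_ic50_se
1,Lys(Har)-GlyΨ[Trl]Arg,linker,1,C22H43N13O4,554.3634,554.3640,28.1,1.2,,
2,D-Lys(Har)-GlyΨ[Trl]Arg,linker,1,C22H43N13O4,554.3634,554.3656,33.1,1.9,,
3,Lys(Har)-GlyΨ[Trl]GlyΨ[Trl]Arg,linker,1,C25H46N16O4,635.3961,635.3979,58.1,2.1,-5.076,0.06
4,D-Lys(Har)-GlyΨ[Trl]GlyΨ[Trl]Arg,linker,1,C25H46N16O4,635.3961,635.3980,52.6,1.3,-4.991,0.05
5,D-Lys(D-Har)-GlyΨ[Trl]GlyΨ[Trl]Arg,linker,1,C25H46N16O4,635.3961,635.3982,48.5,2.9,-5.040,0.1417
6,Lys(Har)-Pro-GlyΨ[Trl]Arg,linker,1,C27H50N14O5,651.4161,651.4187,18.3,0.9,,
7,D-Lys(Har)-Pro-GlyΨ[Trl]Arg,linker,1,C27H50N14O5,651.4161,651.4190,38.4,1.5,,
8,Lys(Har)-Phe-GlyΨ[Trl]Arg,linker,1,C31H52N14O5,701.4318,701.4339,30.9,2.1,,
9,D-Lys(Har)-Phe-GlyΨ[Trl]Arg,linker,1,C31H52N14O5,701.4318,701.4338,37.9,1.1,,
10,Lys(Har)-GlyΨ[Trl]Ala-Arg,linker,1,C25H48N14O5,625.4005,625.3994,43.2,1.5,,
11,Lys(Har)-GlyΨ[Trl]Gly-Arg,linker,1,C24H46N14O5,611.3848,611.3878,30.6,1.1,,
12,Har-Pro-GlyΨ[Trl]Arg,linker,1,C21H38N12O4,523.3212,523.3221,9.2,0.8,,
13,Har-GlyΨ[Trl]GlyΨ[Trl]GlyΨ[Trl]Arg,linker,1,C22H37N17O3,588.3338,588.3362,34.8,1.5,,
14,Lys(Fmoc-Har)-GlyΨ[Trl]GlyΨ[Trl]Arg,arm,2,C40H56N16O6,429.2357,429.2371,57.7,1.8,,
15,D-Lys(Fmoc-Har)-GlyΨ[Trl]GlyΨ[Trl]Arg,arm,2,C40H56N16O6,429.2357,429.2373,43.7,0.5,,
16,Har-Lys-GlyΨ[Trl]GlyΨ[Trl]Arg,arm,1,C25H46N16O4,635.3961,635.3991,36.5,1.4,,
17,Dab(Har)-GlyΨ[Trl]GlyΨ[Trl]Arg,arm,1,C23H42N16O4,607.3648,607.3675,41.3,0.5,,
18,Dap(Har)-GlyΨ[Trl]GlyΨ[Trl]Arg,arm,1,C22H40N16O4,593.3491,593.3517,25.3,3.5,,
19,Har-6Ahx-GlyΨ[Trl]GlyΨ[Trl]]Arg,arm,1,C25H45N15O4,620.3852,620.3878,30.5,0.6,,
20,Har-5Ava-GlyΨ[Trl]GlyΨ[Trl]Arg,arm,1,C24H43N15O4,606.3695,606.3721,29.7,1.8,,
21,Har-Ala-GlyΨ[Trl]GlyΨ[Trl]]Arg,arm,1,C22H39N15O4,578.3382,578.3406,27.8,2.1,,
22,Har-Gly-GlyΨ[Trl]GlyΨ[Trl]Arg,arm,1,C21H37N15O4,564.3226,564.3244,35.7,1.6,,
23,Har-GlyΨ[Trl]GlyΨ[Trl]Arg,arm,1,C19H34N14O3,507.3020,507.3011,20.0,2.1,,
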