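id,name,category,mass_kg,n_per_m3
p01,producer p01,producer,1.3936689126371557e-13,3164382073.5775886
p02,producer p02,producer,2.050366285259464e-13,1535941451.725785
p03,producer p03,producer,2.6504917024335826e-13,1585281001.026062
p04,producer p04,producer,3.2495380354723745e-13,4865660720.285655
p05,producer p05,producer,8.884836640547008e-13,202353199.20327118
p06,producer p06,producer,8.92203035167891e-13,194318132.41177922
i01,invertebrate i01,invertebrate,1.1353198378048267e-10,876726.4952432223
i02,invertebrate i02,invertebrate,6.582612236208865e-10,315993.1102611138
i03,invertebrate i03,invertebrate,1.2565719918271567e-09,254571.61645105894
i04,invertebrate i04,invertebrate,3.2138545457220144e-09,46881.53535855004
i05,invertebrate i05,invertebrate,4.522777132120286e-09,46965.63116327907
v01,vertebrate_ectotherm v01,vertebrate_ectotherm,3.452576524170386e-07,4723.829518187062
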