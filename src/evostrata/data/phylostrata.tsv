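species_code	stratum_name	is_focal
Hs	Vertebrata	1
Gg	Vertebrata	0
Xt	Vertebrata	0
Dr	Vertebrata	0
Ci	Deuterostomia	0
Bf	Deuterostomia	0
Sp	Deuterostomia	0
Lg	Bilateria	0
Ct	Bilateria	0
Hr	Bilateria	0
Sm	Bilateria	0
Pp	Bilateria	0
Ce	Bilateria	0
Dm	Bilateria	0
Dp	Bilateria	0
Is	Bilateria	0
Hm	Parahoxozoa	0
Nv	Parahoxozoa	0
Ta	Parahoxozoa	0
Aq	Metazoa	0
Ml	Metazoa	0
Mb	Filozoa	0
Co	Filozoa	0
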