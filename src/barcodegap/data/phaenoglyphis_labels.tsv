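# record_id	species
P_belizini_CO1	Phaenoglyphis belizini
P_evenhuisi_CO1	Phaenoglyphis evenhuisi
P_longicornis_CO1	Phaenoglyphis longicornis
P_salicis_CO1	Phaenoglyphis salicis
P_stricta_CO1	Phaenoglyphis stricta
P_villosa_CO1	Phaenoglyphis villosa
P_xanthochroa_CO1	Phaenoglyphis xanthochroa
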