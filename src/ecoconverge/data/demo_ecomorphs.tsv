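Myotis_sp01	gleaner
Myotis_sp02	aerial_hawker
Myotis_sp03	aerial_hawker
Myotis_sp04	aerial_hawker
Myotis_sp05	trawler
Myotis_sp06	gleaner
Myotis_sp07	trawler
Myotis_sp08	gleaner
Myotis_sp09	aerial_hawker
Myotis_sp10	aerial_hawker
Myotis_sp11	trawler
Myotis_sp12	trawler
Myotis_sp13	trawler
Myotis_sp14	gleaner
Myotis_sp15	aerial_hawker
Myotis_sp16	trawler
Myotis_sp17	trawler
Myotis_sp18	aerial_hawker
Myotis_sp19	aerial_hawker
Myotis_sp20	trawler
Myotis_sp21	gleaner
Myotis_sp22	aerial_hawker
Outgroup_sp01	outgroup
Outgroup_sp02	outgroup
Outgroup_sp03	outgroup
Outgroup_sp04	outgroup
Outgroup_sp05	outgroup
Outgroup_sp06	outgroup
Outgroup_sp07	outgroup
Outgroup_sp08	outgroup
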