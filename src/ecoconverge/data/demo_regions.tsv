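Myotis_sp01	Nr
Myotis_sp02	Nr
Myotis_sp03	Nr
Myotis_sp04	Nr
Myotis_sp05	Nt
Myotis_sp06	Nt
Myotis_sp07	Nt
Myotis_sp08	Af
Myotis_sp09	Af
Myotis_sp10	Af
Myotis_sp11	WP
Myotis_sp12	WP
Myotis_sp13	WP
Myotis_sp14	EP
Myotis_sp15	EP
Myotis_sp16	EP
Myotis_sp17	IM
Myotis_sp18	IM
Myotis_sp19	IM
Myotis_sp20	Oc
Myotis_sp21	Oc
Myotis_sp22	Oc
Outgroup_sp01	outgroup_range
Outgroup_sp02	outgroup_range
Outgroup_sp03	outgroup_range
Outgroup_sp04	outgroup_range
Outgroup_sp05	outgroup_range
Outgroup_sp06	outgroup_range
Outgroup_sp07	outgroup_range
Outgroup_sp08	outgroup_range
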