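((((((((((((((Myotis_sp01:8.5668360708,(Myotis_sp02:4.5709917893,Myotis_sp03:4.5709917893):3.9958442815):0.9789645734,((Myotis_sp04:0.162380458,Myotis_sp05:0.162380458):5.8384988727,Myotis_sp06:6.0008793307):3.5449213135):5.7748413813,(Myotis_sp07:5.5984815964,(Myotis_sp08:5.0834251889,((Myotis_sp09:3.0439682942,Myotis_sp10:3.0439682942):1.3132297891,Myotis_sp11:4.3571980833):0.7262271056):0.5150564076):9.7221604291):4.2151429153,(Myotis_sp12:10.3610543668,(Myotis_sp13:7.8154166758,Myotis_sp14:7.8154166758):2.5456376909):9.174730574):1.3552404726,((Myotis_sp15:4.8690602829,Myotis_sp16:4.8690602829):10.2845881067,Myotis_sp17:15.1536483896):5.7373770239):1.1089745866,((Myotis_sp18:7.9624694827,Myotis_sp19:7.9624694827):11.8855024886,(Myotis_sp20:4.4704997528,(Myotis_sp21:0.2787589484,Myotis_sp22:0.2787589484):4.1917408044):15.3774722185):2.1520280287):2.504325105,Outgroup_sp01:24.504325105):1.5210782108,Outgroup_sp02:26.0254033158):5.3580203486,Outgroup_sp03:31.3834236644):1.230828122,Outgroup_sp04:32.6142517863):3.2825617687,Outgroup_sp05:35.896813555):4.4113880319,Outgroup_sp06:40.3082015869):7.3522292776,Outgroup_sp07:47.6604308645):4.3395691355,Outgroup_sp08:52.0);
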