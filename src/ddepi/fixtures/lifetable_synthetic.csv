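sex,age,qx
male,0,4.231e-05
male,1,4.6294513943567453e-05
male,2,5.065426663368379e-05
male,3,5.5424595910523695e-05
male,4,6.064416753004799e-05
male,5,6.635528856808903e-05
male,6,7.260425033904136e-05
male,7,7.944170360867436e-05
male,8,8.692306914234289e-05
male,9,9.51089869162815e-05
male,10,0.00010406580763305053
male,11,0.00011386613052509728
male,12,0.00012458939180558232
male,13,0.00013632250853614082
male,14,0.00014916058313042932
male,15,0.00016320767420378897
male,16,0.00017857764001712412
male,17,0.00019539506135150375
male,18,0.0002137962512938172
male,19,0.0002339303601182716
male,20,0.0002559605842193117
male,21,0.0002800654888949326
male,22,0.0003064404557021624
male,23,0.00033529926611621175
male,24,0.00036687583432958883
male,25,0.00040142610323632924
male,26,0.00043923011896918426
male,27,0.00048059430080486153
male,28,0.0005258539248359659
male,29,0.0005753758415409664
male,30,0.0006295614492793694
male,31,0.0006888499478136684
male,32,0.0007537218982293921
male,33,0.0008247031181080764
male,34,0.0009023689435253583
male,35,0.0009873488924196862
male,36,0.0010803317671304426
male,37,0.0011820712374639366
male,38,0.0012933919495406343
male,39,0.001415196209938709
male,40,0.0015484712993120151
male,41,0.001694297474762801
male,42,0.0018538567258321343
male,43,0.0020284423550794616
male,44,0.0022194694609063807
male,45,0.002428486407592828
male,46,0.002657187375515722
male,47,0.0029074260932754423
male,48,0.003181230863035498
male,49,0.0034808210008627732
male,50,0.003808624825325078
male,51,0.0041672993401519485
male,52,0.004559751770495953
male,53,0.0049891631273559734
male,54,0.0054590139911631684
male,55,0.005973112723517686
male,56,0.006535626335745442
male,57,0.0071511142644791765
male,58,0.007824565328030613
male,59,0.00856143816310252
male,60,0.00936770546959915
male,61,0.01024990242216004
male,62,0.011215179640815259
male,63,0.012271361150114294
male,64,0.013427007796514252
male,65,0.014691486638055255
male,66,0.016075046868758776
male,67,0.017588902893151813
male,68,0.0192453252242749
male,69,0.021057739941944806
male,70,0.023040837517428053
male,71,0.025210691886599974
male,72,0.027584890736733283
male,73,0.030182678062951628
male,74,0.033025110149835085
male,75,0.03613522624248147
male,76,0.039538235290392874
male,77,0.04326172027783369
male,78,0.04733586179685385
male,79,0.05179368267514138
male,80,0.056671315641527775
male,81,0.06200829619870059
male,82,0.06784788307699371
male,83,0.07423740886668445
male,84,0.0812286636708353
male,85,0.08887831488836764
male,86,0.09724836652990579
male,87,0.10640666178936149
male,88,0.11642743294483716
male,89,0.1273919030460536
male,90,0.13938894426525927
male,91,0.15251579824786554
male,92,0.16687886430158663
male,93,0.18259456181272754
male,94,0.19979027387990786
male,95,0.21860537981381595
male,96,0.2391923848718879
male,97,0.2617181563849389
male,98,0.2863652762951387
male,99,0.31333352106827805
male,100,1.0
female,0,2.922e-05
female,1,3.197177256986625e-05
female,2,3.4982691350419294e-05
female,3,3.827716125042549e-05
female,4,4.188188549345314e-05
female,5,4.582608206002273e-05
female,6,5.014172051304157e-05
female,7,5.486378112610411e-05
female,8,6.00305384150144e-05
female,9,6.568387137068649e-05
female,10,7.186960290800607e-05
female,11,7.863787128204544e-05
female,12,8.604353648213463e-05
female,13,9.414662489780276e-05
female,14,0.00010301281586081647
female,15,0.0001127139740069656
female,16,0.00012332873177263925
female,17,0.0001349431267475996
female,18,0.0001476512990499962
female,19,0.0001615562543761734
female,20,0.00017677069891014626
female,21,0.00019341795286007872
female,22,0.00021163295002640478
female,23,0.00023156333150356202
female,24,0.0002533706423803022
female,25,0.00027723164113839613
female,26,0.00030333973236302446
female,27,0.0003319065343776425
female,28,0.0003631635945097358
female,29,0.0003973642658904996
female,30,0.0004347857610007841
female,31,0.0004757313986082579
female,32,0.0005205330623082685
female,33,0.0005695538905960292
female,34,0.0006231912202744261
female,35,0.0006818798070551461
female,36,0.0007460953494576114
female,37,0.0008163583445685707
female,38,0.0008932383069150871
female,39,0.0009773583846468701
female,40,0.0010694004104442704
female,41,0.0011701104280919178
female,42,0.0012803047395134712
female,43,0.001400876521281538
female,44,0.0015328030642326744
female,45,0.0016771536948679377
female,46,0.0018350984427456724
female,47,0.002007917524119793
female,48,0.0021970117186929155
female,49,0.002403913723592773
female,50,0.0026303005766012476
female,51,0.002878007249332071
female,52,0.0031490415205363215
female,53,0.0034456002500907958
female,54,0.003770087185577589
female,55,0.004125132445785554
female,56,0.004513613839056531
female,57,0.004938680189271604
female,58,0.005403776858545369
female,59,0.00591267367350167
female,60,0.0064694954814863434
female,61,0.0070787555843894205
female,62,0.00774539232107355
female,63,0.008474809094926487
female,64,0.00927291817097959
female,65,0.010146188597588621
female,66,0.011101698641104501
female,67,0.012147193158541623
female,68,0.013291146373276122
female,69,0.014542830562600502
female,70,0.015912391213879645
female,71,0.01741092925848384
female,72,0.019050591050043645
female,73,0.02084466681634239
female,74,0.022807698382845222
female,75,0.02495559704101415
female,76,0.027305772516787518
female,77,0.0298772740845734
female,78,0.03269094497055234
female,79,0.03576959129680055
female,80,0.039138166935604866
female,81,0.04282397577230043
female,82,0.046856893016066097
female,83,0.05126960735250579
female,84,0.056097885900775406
female,85,0.061380864122857544
female,86,0.06716136303483448
female,87,0.07348623629130567
female,88,0.0804067499562312
female,89,0.08797899803842321
female,90,0.09626435715979383
female,91,0.10532998404165991
female,92,0.11524935984146446
female,93,0.12610288575201842
female,94,0.1379785346908747
female,95,0.15097256436208228
female,96,0.16519029747002045
female,97,0.18074697540931023
female,98,0.19776869235036523
female,99,0.216393417291777
female,100,1.0
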