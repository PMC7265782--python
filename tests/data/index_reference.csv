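seed,n,k,index,value
101,14,2,ball_hall,4.015415885316836
101,14,2,banfeld_raftery,19.514019607870697
101,14,2,c_index,0.0
101,14,2,calinski_harabasz,696.736917749028
101,14,2,davies_bouldin,0.1211059631815433
101,14,2,dunn,4.974342701780442
101,14,2,ksq_detw,2954.6535962419966
101,14,2,log_ss_ratio,4.061501240293052
101,14,2,mcclain_rao,0.09113823033121117
101,14,2,pbm,15524.730140090855
101,14,2,point_biserial,-14.054006981306213
101,14,2,ray_turi,0.00421791272335401
101,14,2,ratkowsky_lance,0.6978886688678129
101,14,2,scott_symons,17.796330804600338
101,14,2,sd_scat,0.01496537128055579
101,14,2,sd_dis,0.06468704666686323
101,14,2,s_dbw,0.01496537128055579
101,14,2,trace_w,56.44831322665165
101,14,2,trace_wib,109.75289346004894
101,14,2,wemmert_gancarski,0.9383153896826555
101,14,2,xie_beni,0.006044396379036724
101,14,2,gdi11,4.974342701780442
101,14,2,gdi12,18.214711879006934
101,14,2,gdi13,6.540577303871928
101,14,2,gdi21,6.5952250339436
101,14,2,gdi22,24.149949244047626
101,14,2,gdi23,8.67181490239903
101,14,2,gdi31,5.965400123361119
101,14,2,gdi32,21.84369895767812
101,14,2,gdi33,7.84368166700805
101,14,2,gdi41,5.954747846190442
101,14,2,gdi42,21.80469316914454
101,14,2,gdi43,7.829675385882275
101,14,2,gdi51,0.3633906118218649
101,14,2,gdi52,1.330639180027181
101,14,2,gdi53,0.4778087338597546
102,20,3,ball_hall,5.325281262311537
102,20,3,banfeld_raftery,32.561733577963516
102,20,3,c_index,0.0
102,20,3,calinski_harabasz,338.93501069169594
102,20,3,davies_bouldin,0.1936194824020056
102,20,3,det_ratio,1241.9631824142948
102,20,3,dunn,2.163742004395532
102,20,3,ksq_detw,22262.454707332086
102,20,3,log_det_ratio,142.4889723653045
102,20,3,log_ss_ratio,3.685742216631631
102,20,3,mcclain_rao,0.122897170081073
102,20,3,pbm,5415.991504027234
102,20,3,point_biserial,-10.388855714848132
102,20,3,ray_turi,0.01419167573327442
102,20,3,ratkowsky_lance,0.5695524601036527
102,20,3,sd_scat,0.02503072700988572
102,20,3,sd_dis,0.1014480829085753
102,20,3,s_dbw,0.02503072700988572
102,20,3,trace_w,103.76032075957023
102,20,3,trace_wib,80.33272128087334
102,20,3,wemmert_gancarski,0.9012439154083409
102,20,3,xie_beni,0.02937670714545952
102,20,3,gdi11,2.163742004395532
102,20,3,gdi12,7.446308097185626
102,20,3,gdi13,2.917603028814286
102,20,3,gdi21,3.779610943756849
102,20,3,gdi22,13.007164217145398
102,20,3,gdi23,5.096450646538723
102,20,3,gdi31,3.127298592848136
102,20,3,gdi32,10.762294574369902
102,20,3,gdi33,4.216868659925719
102,20,3,gdi41,3.113079368805486
102,20,3,gdi42,10.713360494932799
102,20,3,gdi43,4.19769537075818
102,20,3,gdi51,0.3164082694004526
102,20,3,gdi52,1.088888348826633
102,20,3,gdi53,0.4266468568199475
103,28,4,ball_hall,3.404346411204848
103,28,4,banfeld_raftery,32.7156139889141
103,28,4,c_index,0.0384087791801784
103,28,4,calinski_harabasz,174.21806909809857
103,28,4,davies_bouldin,0.9563085327668726
103,28,4,det_ratio,72.34941825097019
103,28,4,dunn,0.06781045806551747
103,28,4,ksq_detw,33198.31960455621
103,28,4,log_det_ratio,119.8822075439677
103,28,4,log_ss_ratio,3.080866243525273
103,28,4,mcclain_rao,0.2151676114110067
103,28,4,pbm,555.096064776155
103,28,4,point_biserial,-3.855174029722606
103,28,4,ray_turi,0.6301274687843618
103,28,4,ratkowsky_lance,0.4791673466166601
103,28,4,scott_symons,18.5622260635531
103,28,4,sd_scat,0.04112765515342311
103,28,4,sd_dis,1.213352261139129
103,28,4,trace_w,94.3301324494553
103,28,4,trace_wib,56.225098156270484
103,28,4,wemmert_gancarski,0.4883896010976646
103,28,4,xie_beni,22.239073100689684
103,28,4,gdi11,0.06781045806551747
103,28,4,gdi12,0.2616031422428747
103,28,4,gdi13,0.09661287045469531
103,28,4,gdi21,1.065034680566828
103,28,4,gdi22,4.10875294139325
103,28,4,gdi23,1.517406909771117
103,28,4,gdi31,0.5133610905931967
103,28,4,gdi32,1.980474372767894
103,28,4,gdi33,0.7314106106471283
103,28,4,gdi41,0.4028476302840634
103,28,4,gdi42,1.554129096511695
103,28,4,gdi43,0.5739566879198932
103,28,4,gdi51,0.2508177112861094
103,28,4,gdi52,0.9676192032092804
103,28,4,gdi53,0.3573522394556786
104,16,2,ball_hall,3.323439952585007
104,16,2,banfeld_raftery,19.31092978903325
104,16,2,c_index,0.0
104,16,2,calinski_harabasz,188.8144522167302
104,16,2,davies_bouldin,0.2469613772586825
104,16,2,det_ratio,34.24592145903242
104,16,2,dunn,1.837170659494336
104,16,2,ksq_detw,2530.7345575132126
104,16,2,log_det_ratio,56.53707961806986
104,16,2,log_ss_ratio,2.601707468924616
104,16,2,mcclain_rao,0.1831271615918144
104,16,2,pbm,750.3248517076609
104,16,2,point_biserial,-5.622715599202659
104,16,2,ray_turi,0.01824708045147575
104,16,2,ratkowsky_lance,0.6713212408533092
104,16,2,scott_symons,6.715440727432028
104,16,2,sd_scat,0.05851207891036886
104,16,2,sd_dis,0.1465033151130087
104,16,2,s_dbw,0.05851207891036886
104,16,2,trace_w,54.40996626014081
104,16,2,trace_wib,33.245921459032424
104,16,2,wemmert_gancarski,0.8732540683099865
104,16,2,xie_beni,0.03548937596510506
104,16,2,gdi11,1.837170659494336
104,16,2,gdi12,7.255530638969206
104,16,2,gdi13,2.611774753378627
104,16,2,gdi21,3.219129759203207
104,16,2,gdi22,12.71329610997875
104,16,2,gdi23,4.576407635015726
104,16,2,gdi31,2.586929894582987
104,16,2,gdi32,10.216551747118793
104,16,2,gdi33,3.677654088647342
104,16,2,gdi41,2.562134880564749
104,16,2,gdi42,10.118628898757764
104,16,2,gdi43,3.642404782172827
104,16,2,gdi51,0.3207910627613422
104,16,2,gdi52,1.266898843906552
104,16,2,gdi53,0.4560458194233181
105,24,3,ball_hall,3.336974175959286
105,24,3,banfeld_raftery,29.120018206300653
105,24,3,c_index,0.01582736727377916
105,24,3,calinski_harabasz,424.07653818708997
105,24,3,davies_bouldin,0.5498958636497279
105,24,3,det_ratio,184.87946325702123
105,24,3,dunn,0.1058002876367671
105,24,3,ksq_detw,11939.406497381435
105,24,3,log_det_ratio,125.27289750636858
105,24,3,log_ss_ratio,3.698538696369875
105,24,3,mcclain_rao,0.1349419217390197
105,24,3,pbm,3643.4985525385346
105,24,3,point_biserial,-7.372585846074666
105,24,3,ray_turi,0.183047757797857
105,24,3,ratkowsky_lance,0.569497060565869
105,24,3,scott_symons,15.934877896841524
105,24,3,sd_scat,0.02242138298768294
105,24,3,sd_dis,0.5369698203419611
105,24,3,trace_w,81.3116522506023
105,24,3,trace_wib,61.36486189846739
105,24,3,wemmert_gancarski,0.6285548321080183
105,24,3,xie_beni,8.427560460914336
105,24,3,gdi11,0.1058002876367671
105,24,3,gdi12,0.4917516019470901
105,24,3,gdi13,0.1880816852276788
105,24,3,gdi21,1.40895986866738
105,24,3,gdi22,6.548737134581922
105,24,3,gdi23,2.504714802165042
105,24,3,gdi31,0.786639490050628
105,24,3,gdi32,3.656239865011567
105,24,3,gdi33,1.398412842347967
105,24,3,gdi41,0.7178861590214844
105,24,3,gdi42,3.336679668834646
105,24,3,gdi43,1.276189711827063
105,24,3,gdi51,0.2556007609443439
105,24,3,gdi52,1.188012683715961
105,24,3,gdi53,0.4543827142411559
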