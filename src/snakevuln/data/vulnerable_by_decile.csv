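country,decile,population_vulnerable
Afghanistan,1,281586
Benin,1,97491
Burkina Faso,1,699570
Burundi,1,10597
Central African Republic,1,1081841
Chad,1,5814
Cote d'Ivoire,1,379448
Democratic Republic of the Congo,1,22586819
Eritrea,1,905464
Ethiopia,1,10422734
Guinea,1,427253
Guinea-Bissau,1,120745
Mozambique,1,3206555
Niger,1,1545113
Sierra Leone,1,154596
Somalia,1,2140834
South Sudan,1,601410
Zambia,1,2125572
Angola,2,3652123
Cameroon,2,1279030
Congo (Brazzaville),2,521800
Djibouti,2,73050
India,2,231656
Liberia,2,664940
Malawi,2,133687
Mali,2,2373844
Senegal,2,467056
Tanzania,2,4950775
The Gambia,2,3245
Togo,2,14488
Uganda,2,371059
Zimbabwe,2,936801
Cambodia,3,43972
Gabon,3,499707
Ghana,3,354713
India,3,1488560
Indonesia,3,10454226
Kenya,3,1825765
Laos,3,18010
Mauritania,3,5129
Myanmar,3,2544010
Namibia,3,752476
Nepal,3,2665443
Nigeria,3,2067928
Pakistan,3,4425880
Rwanda,3,32081
Swaziland,3,226
Yemen,3,3017147
Bangladesh,4,359780
Bhutan,4,114385
Bolivia,4,1307831
Botswana,4,323599
China,4,167314
Equatorial Guinea,4,242345
Guatemala,4,533186
Guyana,4,138904
Honduras,4,58882
India,4,4623346
Iraq,4,49668
Philippines,4,1517133
South Africa,4,289322
Sudan,4,542183
Suriname,4,94635
Tajikistan,4,301870
Algeria,5,74397
Belize,5,14532
Brazil,5,4107300
China,5,6787216
Ecuador,5,552572
Egypt,5,37780
Kyrgyzstan,5,495765
Mexico,5,229259
Morocco,5,93028
Nicaragua,5,73046
Paraguay,5,227331
Uzbekistan,5,805059
Vietnam,5,175519
Argentina,6,78462
Azerbaijan,6,116150
Brazil,6,2296619
China,6,6793121
Colombia,6,6277835
Georgia,6,111973
India,6,276547
Malaysia,6,1790903
Mexico,6,384600
Panama,6,137946
Peru,6,2674949
Syria,6,48738
Trinidad and Tobago,6,6520
Venezuela,6,3346588
Armenia,7,27064
China,7,11323668
Costa Rica,7,138011
Iran,7,341174
Jordan,7,91671
Kazakhstan,7,2494396
Mexico,7,275250
Sri Lanka,7,62951
Thailand,7,77295
Turkey,7,48653
Brunei,8,9630
China,8,8414197
Oman,8,84388
Russia,8,1205085
Saudi Arabia,8,2392280
Ukraine,8,4956
China,9,14142
Greece,9,7327
Japan,9,38825
USA,9,4728
Japan,10,6288
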