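patient_id,route,scan_index,time_min,suv_max_tumour,suv_mean_background,suv_mean_parotid,suv_mean_liver,body_weight_kg,injected_activity_mbq,tumour_ce_volume_ml,uptake_volume_ml,ref_tbr_max,ref_tsg_ratio,ref_tl_ratio
1,IV,1,90,3.6,,12.4,6,,,,,359,0.4,1
1,IV,2,165,5.9,<0.01,15.4,,,,,,,,
1,IV,3,241,5.8,<0.01,17.4,,,,,,,,
1,ssIA,1,94,131,<0.01,13,5,,,,,,9.2,27.4
1,ssIA,2,165,136,<0.01,15.7,,,,,,,,
1,ssIA,3,240,111,<0.01,15.8,,,,,,,,
2,IV,1,92,6.5,<0.01,12,6.1,,,,,,0.7,1.5
2,IV,2,165,9,<0.01,12.9,,,,,,,,
2,IV,3,241,9,<0.01,13.2,,,,,,,,
2,ssIA,1,93,231.7,,19,9.1,,,,,3604,11.1,25.5
2,ssIA,2,166,200.4,,21.9,,,,,,2671,,
2,ssIA,3,242,196.7,,21.9,,,,,,6116,,
3,IV,1,90,7.3,<0.01,18.8,8.7,,,,,,0.5,1
3,IV,2,165,7.7,<0.01,18.9,,,,,,,,
3,IV,3,240,9.1,<0.01,21.3,,,,,,,,
3,ssIA,1,90,,,22.2,7.5,,,,,,5.2,16.1
3,ssIA,2,165,120.2,<0.01,24.6,,,,,,,,
3,ssIA,3,240,118.2,,23.3,,,,,,10626,,
4,IV,1,90,8.1,,18.1,3.9,,,,,269,0.4,2
4,IV,2,165,8,,19.4,,,,,,265,,
4,IV,3,263,6.6,,20.7,,,,,,329,,
4,ssIA,1,91,31.3,,17.8,4,,,,,988,1.8,7.9
4,ssIA,2,165,21.7,,17.6,,,,,,1027,,
4,ssIA,3,240,24.6,,18.1,,,,,,2328,,
5,IV,1,91,7.1,,11,5.2,,,,,710,1.1,2.5
5,IV,2,167,8.4,,11.6,,,,,,840,,
5,IV,3,245,12.7,,12.8,,,,,,1269,,
5,ssIA,1,143,149.5,,10.6,6.5,,,,,13071,12.8,23
5,ssIA,2,205,145,,11.9,,,,,,12680,,
5,ssIA,3,241,135,,12.6,,,,,,11803,,
6,IV,1,90,10.7,,17.9,2.4,,,,,1067,0.9,7
6,IV,2,165,11.3,,19.8,,,,,,1131,,
6,IV,3,240,17.1,,21.7,,,,,,1705,,
6,ssIA,1,105,127,,18.7,2.9,,,,,1553,6.5,44.3
6,ssIA,2,166,128.6,,19.3,,,,,,2096,,
6,ssIA,3,249,110.9,,21.3,,,,,,1809,,
7,IV,1,91,7.7,,21.8,3.7,,,,,769,0.5,3.3
7,IV,2,168,8.9,,25.8,,,,,,886,,
7,IV,3,249,12,,28.9,,,,,,1196,,
7,ssIA,1,91,288.5,,26,4.2,,,,,12880,9.7,68.7
7,ssIA,2,165,211,,31.6,,,,,,6281,,
7,ssIA,3,240,225,,31.3,,,,,,5022,,
8,IV,1,93,13.1,,29.7,7.5,,,,,1311,0.4,1.8
8,IV,2,165,10.8,,34.7,,,,,,1080,,
8,IV,3,240,10.7,,35.1,,,,,,1070,,
8,ssIA,1,93,215.2,,26,7.3,,,,,10152,7.6,29.7
8,ssIA,2,165,180.4,,29.2,,,,,,5674,,
8,ssIA,3,240,175.5,,30.4,,,,,,8279,,
9,IV,1,92,8.7,,23.8,6.7,,,,,290,0.5,1.9
9,IV,2,165,10,,28.4,,,,,,995,,
9,IV,3,240,13,,32.3,,,,,,1291,,
9,ssIA,1,102,49.1,,18.4,6.8,,,,,882,2.2,7.4
9,ssIA,2,165,46.6,,23.7,,,,,,1046,,
9,ssIA,3,240,50.5,,26.4,,,,,,1133,,
10,IV,1,91,4,,13.2,6,,,,,397,0.4,0.9
10,IV,2,165,4.8,,14.8,,,,,,478,,
10,IV,3,240,5.1,,15.4,,,,,,171,,
10,ssIA,1,90,336.8,,17.4,6.4,,,,,30191,18.9,52.8
10,ssIA,2,165,277.6,<0.01,18.6,,,,,,,,
10,ssIA,3,240,282.7,<0.01,17.5,,,,,,,,
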