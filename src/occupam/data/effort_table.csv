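forest,year,arus,grid_cells,survey_hours,detections
Lassen,2021,235,120,73157,1172
Lassen,2022,230,114,66329,814
Lassen,2023,213,93,71101,158
Lassen,2024,249,119,82464,485
Plumas,2021,268,147,83356,1069
Plumas,2022,323,144,73169,1092
Plumas,2023,310,131,101213,1573
Plumas,2024,316,139,102235,2742
Tahoe,2021,235,119,82255,4121
Tahoe,2022,197,103,73433,3970
Tahoe,2023,170,87,58750,1608
Tahoe,2024,181,93,55180,2196
Eldorado,2021,207,103,71975,1856
Eldorado,2022,210,107,72928,1728
Eldorado,2023,202,100,71537,2571
Eldorado,2024,213,107,69327,3320
Stanislaus,2021,184,93,62583,4549
Stanislaus,2022,212,97,72159,4398
Stanislaus,2023,136,63,43797,2485
Stanislaus,2024,168,78,61125,5717
Sierra,2021,222,113,72965,954
Sierra,2022,268,128,94682,2544
Sierra,2023,154,80,39768,486
Sierra,2024,216,106,75719,2265
Sequoia,2021,125,63,44532,3566
Sequoia,2022,176,85,62992,2989
Sequoia,2023,139,70,39534,849
Sequoia,2024,163,82,58211,2432
All forests,2021,1476,758,490823,17287
All forests,2022,1616,778,515692,17535
All forests,2023,1324,624,425700,9730
All forests,2024,1506,724,504261,19157
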