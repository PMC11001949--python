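class_code,class_name,year,area_ha
1.1.1,Continuous urban fabric,1958,NA
1.1.1,Continuous urban fabric,1990,230
1.1.1,Continuous urban fabric,2000,239
1.1.1,Continuous urban fabric,2006,194
1.1.1,Continuous urban fabric,2012,203
1.1.1,Continuous urban fabric,2018,205
1.1.2,Discontinuous urban fabric,1958,NA
1.1.2,Discontinuous urban fabric,1990,424
1.1.2,Discontinuous urban fabric,2000,448
1.1.2,Discontinuous urban fabric,2006,448
1.1.2,Discontinuous urban fabric,2012,436
1.1.2,Discontinuous urban fabric,2018,436
2.1.1,Non-irrigated arable land,1958,13637
2.1.1,Non-irrigated arable land,1990,658
2.1.1,Non-irrigated arable land,2000,658
2.1.1,Non-irrigated arable land,2006,954
2.1.1,Non-irrigated arable land,2012,1153
2.1.1,Non-irrigated arable land,2018,1111
2.1.2,Irrigated arable land,1958,179
2.1.2,Irrigated arable land,1990,0
2.1.2,Irrigated arable land,2000,0
2.1.2,Irrigated arable land,2006,0
2.1.2,Irrigated arable land,2012,0
2.1.2,Irrigated arable land,2018,0
2.2.1,Vineyards,1958,269
2.2.1,Vineyards,1990,0
2.2.1,Vineyards,2000,0
2.2.1,Vineyards,2006,0
2.2.1,Vineyards,2012,0
2.2.1,Vineyards,2018,0
2.2.2,Fruit trees and berry plantations,1958,9304
2.2.2,Fruit trees and berry plantations,1990,8658
2.2.2,Fruit trees and berry plantations,2000,8646
2.2.2,Fruit trees and berry plantations,2006,9387
2.2.2,Fruit trees and berry plantations,2012,9484
2.2.2,Fruit trees and berry plantations,2018,150
2.2.3,Olive groves,1958,2962
2.2.3,Olive groves,1990,3991
2.2.3,Olive groves,2000,3970
2.2.3,Olive groves,2006,3970
2.2.3,Olive groves,2012,3870
2.2.3,Olive groves,2018,2809
2.3.1,Pastures and uncultivated productive land,1958,6804
2.3.1,Pastures and uncultivated productive land,1990,0
2.3.1,Pastures and uncultivated productive land,2000,0
2.3.1,Pastures and uncultivated productive land,2006,0
2.3.1,Pastures and uncultivated productive land,2012,0
2.3.1,Pastures and uncultivated productive land,2018,0
2.4.1,Annual crops associated with permanent crops,1958,2362
2.4.1,Annual crops associated with permanent crops,1990,192
2.4.1,Annual crops associated with permanent crops,2000,192
2.4.1,Annual crops associated with permanent crops,2006,192
2.4.1,Annual crops associated with permanent crops,2012,80
2.4.1,Annual crops associated with permanent crops,2018,119
2.4.2,Complex cultivation patterns,1958,NA
2.4.2,Complex cultivation patterns,1990,134
2.4.2,Complex cultivation patterns,2000,134
2.4.2,Complex cultivation patterns,2006,134
2.4.2,Complex cultivation patterns,2012,110
2.4.2,Complex cultivation patterns,2018,68
2.4.3,"Land mainly occupied by agriculture, with significant areas of natural vegetation",1958,NA
2.4.3,"Land mainly occupied by agriculture, with significant areas of natural vegetation",1990,1623
2.4.3,"Land mainly occupied by agriculture, with significant areas of natural vegetation",2000,1623
2.4.3,"Land mainly occupied by agriculture, with significant areas of natural vegetation",2006,3720
2.4.3,"Land mainly occupied by agriculture, with significant areas of natural vegetation",2012,1932
2.4.3,"Land mainly occupied by agriculture, with significant areas of natural vegetation",2018,12792
3.1.1,Broad-leaved forest,1958,5948
3.1.1,Broad-leaved forest,1990,9125
3.1.1,Broad-leaved forest,2000,9125
3.1.1,Broad-leaved forest,2006,7124
3.1.1,Broad-leaved forest,2012,11912
3.1.1,Broad-leaved forest,2018,9316
3.1.2,Coniferous forest,1958,NA
3.1.2,Coniferous forest,1990,74
3.1.2,Coniferous forest,2000,74
3.1.2,Coniferous forest,2006,130
3.1.2,Coniferous forest,2012,72
3.1.2,Coniferous forest,2018,72
3.1.3,Mixed forest,1958,798
3.1.3,Mixed forest,1990,784
3.1.3,Mixed forest,2000,784
3.1.3,Mixed forest,2006,1263
3.1.3,Mixed forest,2012,1506
3.1.3,Mixed forest,2018,4149
3.2.1,Natural grassland,1958,NA
3.2.1,Natural grassland,1990,4264
3.2.1,Natural grassland,2000,4264
3.2.1,Natural grassland,2006,4907
3.2.1,Natural grassland,2012,6440
3.2.1,Natural grassland,2018,2575
3.2.2,Moors and heathland,1958,NA
3.2.2,Moors and heathland,1990,3118
3.2.2,Moors and heathland,2000,3118
3.2.2,Moors and heathland,2006,NA
3.2.2,Moors and heathland,2012,NA
3.2.2,Moors and heathland,2018,2642
3.2.3,Sclerophylous vegetation,1958,NA
3.2.3,Sclerophylous vegetation,1990,1545
3.2.3,Sclerophylous vegetation,2000,1545
3.2.3,Sclerophylous vegetation,2006,4501
3.2.3,Sclerophylous vegetation,2012,5018
3.2.3,Sclerophylous vegetation,2018,51
3.2.4,Transitional woodland/shrub,1958,NA
3.2.4,Transitional woodland/shrub,1990,6630
3.2.4,Transitional woodland/shrub,2000,6630
3.2.4,Transitional woodland/shrub,2006,5352
3.2.4,Transitional woodland/shrub,2012,75
3.2.4,Transitional woodland/shrub,2018,61
3.3.2,Bare rock,1958,NA
3.3.2,Bare rock,1990,86
3.3.2,Bare rock,2000,86
3.3.2,Bare rock,2006,NA
3.3.2,Bare rock,2012,NA
3.3.2,Bare rock,2018,NA
3.3.3,Sparsely vegetated areas,1958,NA
3.3.3,Sparsely vegetated areas,1990,710
3.3.3,Sparsely vegetated areas,2000,710
3.3.3,Sparsely vegetated areas,2006,43
3.3.3,Sparsely vegetated areas,2012,NA
3.3.3,Sparsely vegetated areas,2018,5766
5.1.1,Water courses,1958,NA
5.1.1,Water courses,1990,112
5.1.1,Water courses,2000,112
5.1.1,Water courses,2006,38
5.1.1,Water courses,2012,41
5.1.1,Water courses,2018,NA
5.1.2,Water bodies,1958,NA
5.1.2,Water bodies,1990,9
5.1.2,Water bodies,2000,9
5.1.2,Water bodies,2006,9
5.1.2,Water bodies,2012,36
5.1.2,Water bodies,2018,36
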