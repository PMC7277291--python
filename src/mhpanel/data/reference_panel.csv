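id,chromosome,start,end,length_bp,snp_ids,triallelic_snp,ae,ho,pd,pe
mh02zha012,2,146369062,146369166,105,rs949778;rs867005;rs952210,rs949778,3.021,0.70,0.801,0.428
mh03zha001,3,25069341,25069517,177,rs4858685;rs4858686;rs75773180;rs9838878,rs4858686,3.247,0.72,0.838,0.460
mh04zha001,4,9589873,9589956,84,rs6830692;rs9714725;rs12501341;rs10939388,rs6830692,2.818,0.70,0.803,0.428
mh04zha002,4,14837753,14837841,89,rs10939597;rs79276692;rs62409414;rs62409415,rs62409414,4.647,0.84,0.858,0.675
mh04zha004,4,57939863,57940018,156,rs10049992;rs1914740;rs1714017;rs6835177,rs1914740,3.709,0.68,0.887,0.398
mh04zha007,4,115480309,115480387,79,rs6819048;rs62308082;rs74383997,rs6819048,3.484,0.74,0.854,0.493
mh05zha004,5,174968560,174968732,173,rs2457087;rs2644662;rs2662178,rs2662178,3.251,0.70,0.846,0.428
mh07zha003,7,41441508,41441607,100,rs4724041;rs378367;rs433709;rs404569,rs433709,4.129,0.76,0.902,0.527
mh07zha004,7,44191190,44191346,157,rs6971410;rs2971679;rs3808323,rs6971410,3.971,0.76,0.889,0.527
mh07zha009,7,103851964,103852139,176,rs144858626;rs149890778;rs11773043;rs7792859,rs7792859,3.133,0.64,0.856,0.342
mh08zha011,8,13728306,13728400,95,rs4831247;rs13265601;rs4831248;rs13268053,rs4831248,4.219,0.86,0.887,0.715
mh09zha008,9,115934698,115934852,155,rs11506774;rs10981667;rs10739387,rs11506774,3.820,0.66,0.878,0.369
mh10zha002,10,20178703,20178809,107,rs10764175;rs148665640;rs10827896;rs10827897,rs10827897,3.903,0.82,0.862,0.637
mh11zha006a,11,124823941,124824066,126,rs3809057;rs3809056;rs3809055;rs3809054,rs3809056,3.834,0.76,0.876,0.527
mh14zha003,14,72252135,72252142,8,rs4902946;rs8012670;rs4902947,rs4902947,3.674,0.70,0.886,0.428
mh16zha009,16,86921457,86921568,112,rs76047588;rs11641186;rs11641193;rs80213582,rs11641186,3.519,0.88,0.876,0.755
mh17zha001,17,239921,240040,120,rs56023444;rs4131415;rs4260117,rs4131415,3.808,0.64,0.874,0.562
mh19zha007,19,28888223,28888363,141,rs8106726;rs8102417;rs59490836;rs10406130,rs8106726,4.995,0.82,0.916,0.637
mh19zha009,19,53632326,53632503,178,rs74178308;rs8108729;rs8107824;rs8108835;rs2560950,rs8107824,3.737,0.80,0.867,0.599
mh22zha008,22,50502766,50502888,123,rs11568183;rs8142282;rs8136173,,3.559,0.76,0.858,0.527
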