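class,Fp1,AF7,AF3,F1,F3,F5,F7,FT7,FC5,FC3,FC1,C1,C3,C5,T7,TP7,CP5,CP3,CP1,P1,P3,P5,P7,P9,PO7,PO3,O1,Iz,Oz,POz,Pz,CPz,Fpz,Fp2,AF8,AF4,AFz,Fz,F2,F4,F6,F8,FT8,FC6,FC4,FC2,FCz,Cz,C2,C4,C6,T8,TP8,CP6,CP4,CP2,P2,P4,P6,P8,P10,PO8,PO4,O2
A,0.1768740516,0.2539647119,0.1588308305,0.09860085683,0.1504803216,0.2184109665,0.2906797,0.2772715863,0.1883666467,0.09907807429,0.05710972541,-0.04440073534,-0.008051089792,0.09070160714,0.2133648443,0.1136931726,-0.01863059302,-0.130649359,-0.1661878444,-0.2398026635,-0.2103443188,-0.1191275899,0.009527869841,0.1724086785,-0.06271333213,-0.1928437372,-0.08050415008,0.1299457996,-0.04819830222,-0.1812374368,-0.2110159023,-0.1384131513,0.07626154569,-0.02334707597,-0.0943027788,-0.06603968144,0.04389907148,0.05177286065,-0.003630391934,-0.068092903,-0.1195666081,-0.1173158733,-0.09150512638,-0.102899121,-0.04560578941,0.01265033827,0.04270220814,-0.02819357888,-0.01222774044,-0.03187247368,-0.05976751863,-0.03534750539,0.02257447644,-0.02475673506,-0.04985573142,-0.08257328689,-0.1496925208,-0.08073523477,-0.01564217092,0.05548382898,0.1696401895,0.04877041333,-0.07433387791,0.006359553726
B,0.1251605542,0.1387275683,0.1739013137,0.1576317452,0.1983122132,0.1970072345,0.1477989025,0.1498896416,0.2083046839,0.2009041866,0.1280310976,0.07350564651,0.1693837716,0.1932989314,0.1372529289,0.1012579378,0.1360148833,0.1033848391,0.01310250929,-0.06168558715,0.01059968144,0.04929739817,0.04017619754,-0.02550711443,-0.0364914288,-0.06546555648,-0.1111092245,-0.1661254307,-0.1660347253,-0.1551819028,-0.1298169493,-0.09159934203,0.1056897012,0.07890907274,0.04575436392,0.0753161046,0.1320558803,0.1003891346,0.05272792287,0.02511276301,0.01766208528,0.008312426246,-0.03193487323,-0.0328604451,-0.04717675598,-0.03454020503,0.03214853572,-0.03799728642,-0.104124846,-0.1087976099,-0.08488220554,-0.07446748066,-0.1180032299,-0.1305977519,-0.1530333826,-0.1494545615,-0.1723425534,-0.1813801063,-0.1699156953,-0.1579846295,-0.159843134,-0.1858601788,-0.1917796451,-0.1910280191
C,0.1070532718,0.1048970467,0.0908885839,0.0230755884,0.03609711021,0.04935513012,0.04945591,-0.04355091928,-0.04267032025,-0.05106658787,-0.04727200476,-0.09434002893,-0.1279836199,-0.1391041442,-0.141312613,-0.2129706496,-0.2024959906,-0.1686733597,-0.1112377604,-0.1014533277,-0.1713770786,-0.2181353862,-0.242493925,-0.2458050867,-0.2265628542,-0.1616221145,-0.1659623229,-0.109295897,-0.06577797991,-0.02692073457,-0.01235882993,-0.02197015799,0.06710408716,0.01616589671,-0.01108733984,0.006395032692,0.05170473613,0.01094666854,0.005138917766,0.005686091823,0.009038368536,0.007549083214,0.07136460805,0.0709622422,0.04591713559,0.01002356757,-0.02465526629,-0.03413369036,0.04227590402,0.1154424519,0.1606141505,0.1552157017,0.218856071,0.2306862873,0.1743663425,0.08276948805,0.08586826854,0.1756026462,0.2296390834,0.2263527109,0.1383800314,0.1658259302,0.1254547162,0.05612112928
D,-0.1617379865,-0.1133576181,-0.1290143384,-0.1048832781,-0.07353138734,-0.06307768741,-0.07883668913,-0.06438175921,-0.02468112639,-0.00892010102,-0.01860972133,0.06283328215,0.04068782889,-0.002008897368,-0.066777828,-0.08025205885,-0.009686999239,0.05999543907,0.110163936,0.09135244724,0.03604983789,-0.03045023869,-0.09966487549,-0.1720719204,-0.1171254123,-0.02937081118,-0.1189678119,-0.1667990787,-0.08917146339,0.03631434012,0.1416637909,0.1610310086,-0.2042091754,-0.2130959353,-0.1678467549,-0.1956613974,-0.190259751,-0.1315492556,-0.1397248609,-0.1203159778,-0.09224096241,-0.0705987522,0.04904013973,0.04875125248,0.02342008101,-0.009296759246,-0.02916916417,0.0875250908,0.1278400304,0.1686340134,0.1807489668,0.1462947873,0.1839022162,0.2363052386,0.2435023036,0.210763246,0.1826222747,0.208517838,0.1991176897,0.1516311608,0.04727073323,0.07039633458,0.1022553333,-0.02128280677
E,-0.2321187356,-0.1878506915,-0.2571308013,-0.2284841673,-0.2221156164,-0.1709184667,-0.09434338734,0.02164529383,-0.06224482288,-0.1350951525,-0.1513684522,-0.07421116554,-0.03859865773,0.04322607438,0.1285158335,0.1986523188,0.1279826989,0.03492412562,-0.02202832164,0.002512296638,0.06740124191,0.1482330966,0.2163364406,0.2518909031,0.1828004013,0.08268681153,0.117571603,0.1264048314,0.05240307909,-0.009966779465,-0.03335340587,-0.03303673777,-0.2137650265,-0.1379934848,-0.02809779797,-0.1124190013,-0.2339674413,-0.1862457539,-0.1139177218,-0.0291355501,0.03962908975,0.08092137232,0.1546728366,0.1263733622,0.06031131272,-0.02329436219,-0.1088806817,-0.05072288945,0.01283176422,0.08588425233,0.1439040123,0.1731533891,0.1399444975,0.1032889534,0.0488517784,-0.001599503126,-0.035851778,-0.008500209238,0.0351749681,0.0805393799,0.122437909,0.0304204176,-0.02251146594,0.01824168334
F,-0.03316603434,-0.07256862486,-0.08082922109,-0.07428948484,-0.1224643753,-0.1132733099,-0.05512686065,0.003497270344,-0.0903456292,-0.1489700212,-0.1349839093,-0.1801995837,-0.1483579131,-0.05109341149,0.07335672347,0.1252215256,0.007656998255,-0.1183273436,-0.1863358123,-0.1356854695,-0.06586475713,0.03740654478,0.1430551831,0.2340753529,0.1263266119,0.0023111832,0.08528267244,0.1220875886,0.03434854534,-0.07608671655,-0.1704443024,-0.1987276266,0.05462922951,0.1597686738,0.2407396215,0.180396504,0.03770076997,0.009571415275,0.1045840547,0.1861977058,0.2417055559,0.2642490404,0.2218309867,0.1932494973,0.1248788675,0.03795703225,-0.05858332945,-0.1474751226,-0.07703099139,0.004458594143,0.0790808647,0.1351340477,0.04372616906,-0.024742061,-0.1021839666,-0.1630468338,-0.1691520858,-0.1380689735,-0.08259236519,-0.0174196058,0.06248048966,-0.0336396812,-0.09491282382,-0.01097707262
G,0.1510102104,0.1739769797,0.1102606309,0.03320237297,0.09213235269,0.1411333063,0.1730410712,0.1557018583,0.1385727643,0.1001584767,0.04281297914,0.06650642065,0.1152747064,0.1318283202,0.1337686065,0.1191795108,0.1264687706,0.1216373024,0.08237123115,0.08100459203,0.1164669933,0.1240547567,0.117916622,0.1109817124,0.1240845297,0.1139990302,0.1202777738,0.1044595132,0.08792927961,0.05080740126,0.01645034797,-0.004089733535,0.1026552384,0.0347161275,-0.04115033041,-0.049274761,0.02776519095,-0.02976850694,-0.08783841104,-0.1316840347,-0.1406920019,-0.1118420865,-0.1659224337,-0.2084476957,-0.1968576794,-0.1317530218,-0.04046649501,-0.02261130314,-0.1337543877,-0.2222189917,-0.2444525351,-0.1936834561,-0.1863951376,-0.2282268913,-0.2033528994,-0.1168865443,-0.06294341046,-0.1340891715,-0.1627655592,-0.1400878955,-0.06007116126,-0.06316299045,-0.0499348067,0.02181735281
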