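SPECIES,SOURCE_CLASS,DECLATITUDE,DECLONGITUDE,COORD_SYSTEM,UTM_RESOLUTION_M,LOCALITY,COUNTRY,ADM1,ADM2,ADM3,RECORD_ID
Ae. neglecta,external,41.700833,-0.045000,DD,,Villanueva de Sigena,Spain,Huesca,,Villanueva de Sigena,SITE001
Ae. neglecta,external,42.060000,-0.460000,DD,,,Spain,Huesca,,,SITE002
Ae. neglecta,external,41.530000,-0.840000,DD,,El Burgo de Ebro,Spain,Navarra,,El Burgo de Ebro,SITE003
Ae. neglecta,external,41.430000,-0.360000,DD,,Pina de Ebro,Spain,Zaragoza,,Pina de Ebro,SITE004
Ae. neglecta,external,41.430000,-0.720000,DD,,,Spain,Zaragoza,,,SITE005
Ae. neglecta,external,41.420000,-0.240000,DD,,Bujaraloz,Spain,Zaragoza,,Bujaraloz,SITE006
Ae. neglecta,external,41.510000,-0.240000,DD,,La Almolda,Spain,Zaragoza,,La Almolda,SITE007
Ae. geniculata,external,38.640000,-0.900000,DD,,Villena,Spain,Alicante,,Villena,SITE008
Ae. geniculata,external,36.736490,-4.118400,DD,,Velez-Malaga,Spain,Malaga,,Velez-Malaga,SITE009
Ae. neglecta,external,41.430000,-0.480000,DD,,,Spain,Zaragoza,,,SITE010
Ae. neglecta,external,41.520000,-0.600000,DD,,Osera de Ebro,Spain,Zaragoza,,Osera de Ebro,SITE011
Ae. geniculata,external,39.137000,-0.512550,DD,,Alberic,Spain,Valencia,,Alberic,SITE012
Ae. geniculata,external,39.227020,-0.509370,DD,,Alginet,Spain,Valencia,,Alginet,SITE013
Ae. geniculata,external,39.936200,-0.037130,DD,,Vila-real,Spain,Castellon,,Vila-real,SITE014
Ae. geniculata,external,39.450000,-0.440000,DD,,Burjassot,Spain,Valencia,,Burjassot,SITE015
Ae. geniculata,external,39.494530,-0.383580,DD,,Valencia,Spain,Valencia,,Valencia,SITE016
Ae. geniculata,external,39.671850,-0.260330,DD,,Sagunt,Spain,Valencia,,Sagunt,SITE017
Ae. geniculata,external,39.260000,-0.330000,DD,,Valencia,Spain,Valencia,,Valencia,SITE018
Ae. geniculata,external,38.603590,-0.875550,DD,,Villena,Spain,Alicante,,Villena,SITE019
Ae. geniculata,external,39.857140,-0.486740,DD,,Segorbe,Spain,Castellon,,Segorbe,SITE020
Ae. geniculata,external,38.856240,-0.061490,DD,,Pego,Spain,Alicante,,Pego,SITE021
Ae. geniculata,external,40.487170,0.463370,DD,,Vinaros,Spain,Castellon,,Vinaros,SITE022
Ae. geniculata,external,38.810000,0.173000,DD,,Javea,Spain,Alicante,,Javea,SITE023
Ae. neglecta,external,41.710000,-4.680000,DD,,Cabezon de Pisuerga,Spain,Valladolid,,Cabezon de Pisuerga,SITE024
Ae. geniculata,external,36.706040,-4.610470,DD,,Cartama,Spain,Malaga,,Cartama,SITE025
Ae. neglecta,external,42.270278,3.144444,DD,,Roses,Spain,Gerona,,Roses,SITE026
Ae. neglecta,external,41.360000,2.040000,DD,,Barcelona,Spain,Barcelona,,Barcelona,SITE027
Ae. neglecta,external,42.080000,-4.570000,DD,,Monzon de Campos,Spain,Palencia,,Monzon de Campos,SITE028
Ae. biuncialis,external,37.021190,-4.528030,DD,,Antequera,Spain,Malaga,,Antequera,SITE029
Ae. geniculata,external,38.691500,-0.757980,DD,,Beneixama,Spain,Alicante,,Beneixama,SITE030
Ae. geniculata,external,39.540000,-0.550000,DD,,Betera,Spain,Valencia,,Betera,SITE031
Ae. geniculata,external,37.930000,-1.170000,DD,,Murcia,Spain,Murcia,,Murcia,SITE032
Ae. ventricosa,external,38.869280,-6.637140,DD,,Lobon,Spain,Badajoz,,Lobon,SITE033
Ae. neglecta,external,41.330000,-0.250000,DD,,Bujaraloz,Spain,Zaragoza,,Bujaraloz,SITE034
Ae. geniculata,external,39.046980,-0.515710,DD,,Villanueva de Castellon,Spain,Valencia,,Villanueva de Castellon,SITE035
Ae. neglecta,external,41.710000,-0.830000,DD,,,Spain,Zaragoza,,,SITE036
Ae. geniculata,external,39.584530,-0.380200,DD,,Valencia,Spain,Valencia,,Valencia,SITE037
Ae. geniculata,external,36.727000,-4.405000,DD,,Malaga,Spain,Malaga,,Malaga,SITE038
Ae. ventricosa,external,38.414300,-0.423030,DD,,El Campello,Spain,Alicante,,El Campello,SITE039
Ae. triuncialis,external,41.790000,0.710000,DD,,Castellon de Farfana,Spain,Lerida,,Castellon de Farfana,SITE040
Ae. biuncialis,external,36.850000,-2.330000,DD,,Almeria,Spain,Almeria,,Almeria,SITE041
Ae. triuncialis,external,38.384490,-2.804990,DD,,La Puerta de Segura,Spain,Jaen,,La Puerta de Segura,SITE042
Ae. triuncialis,external,40.030000,-0.250000,DD,,Onda,Spain,Castellon,,Onda,SITE043
Ae. triuncialis,external,39.419940,-1.199440,DD,,Requena,Spain,Valencia,,Requena,SITE044
Ae. triuncialis,external,39.190000,-1.490000,DD,,Casas Ibanez,Spain,Albacete,,Casas Ibanez,SITE045
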