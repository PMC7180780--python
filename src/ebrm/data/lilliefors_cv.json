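{
 "alphas": [
  0.2,
  0.15,
  0.1,
  0.05,
  0.01
 ],
 "n_grid": [
  4,
  5,
  6,
  7,
  8,
  9,
  10,
  11,
  12,
  13,
  14,
  15,
  16,
  17,
  18,
  19,
  20,
  25,
  30,
  35,
  40,
  50,
  60,
  80,
  100,
  150,
  200,
  300,
  500
 ],
 "n_sim": 100000,
 "seed": 20200408,
 "cv": {
  "4": {
   "0.2": 0.3029765757932839,
   "0.15": 0.3216940092815438,
   "0.1": 0.34571287097113945,
   "0.05": 0.3749149315152267,
   "0.01": 0.413169739644603
  },
  "5": {
   "0.2": 0.28965617461056736,
   "0.15": 0.3026045593512505,
   "0.1": 0.3186221686799513,
   "0.05": 0.34265280476083054,
   "0.01": 0.39468374088566005
  },
  "6": {
   "0.2": 0.2693165811679775,
   "0.15": 0.28186071269874313,
   "0.1": 0.2979063537410935,
   "0.05": 0.3244124937053639,
   "0.01": 0.3688488847773427
  },
  "7": {
   "0.2": 0.25246612991742645,
   "0.15": 0.26456831840065653,
   "0.1": 0.2804832961254982,
   "0.05": 0.30432074718192464,
   "0.01": 0.35024507688836576
  },
  "8": {
   "0.2": 0.23854712079948942,
   "0.15": 0.25000940698360036,
   "0.1": 0.2651442486964632,
   "0.05": 0.28813216692373805,
   "0.01": 0.3321717387238183
  },
  "9": {
   "0.2": 0.22735931388832425,
   "0.15": 0.23833281188389435,
   "0.1": 0.2524810790374391,
   "0.05": 0.27462285750052673,
   "0.01": 0.3177116118334912
  },
  "10": {
   "0.2": 0.2173069149762231,
   "0.15": 0.2276090958869139,
   "0.1": 0.24123681772076447,
   "0.05": 0.2622914211907503,
   "0.01": 0.3025142190865785
  },
  "11": {
   "0.2": 0.20811798402452933,
   "0.15": 0.21781216945540482,
   "0.1": 0.2307619364207702,
   "0.05": 0.2511919571188124,
   "0.01": 0.29148939915667177
  },
  "12": {
   "0.2": 0.2001613316811684,
   "0.15": 0.20956335583847668,
   "0.1": 0.22214998282081555,
   "0.05": 0.24166669428341314,
   "0.01": 0.2800887961405572
  },
  "13": {
   "0.2": 0.19331106289176517,
   "0.15": 0.20266905377314612,
   "0.1": 0.21487576306858153,
   "0.05": 0.23351819334449236,
   "0.01": 0.2706866803474577
  },
  "14": {
   "0.2": 0.1867896653153231,
   "0.15": 0.19569907119072424,
   "0.1": 0.2075420509516703,
   "0.05": 0.22571371948259514,
   "0.01": 0.2616631620498567
  },
  "15": {
   "0.2": 0.180935671487092,
   "0.15": 0.18983669603964123,
   "0.1": 0.20101830509833804,
   "0.05": 0.21881327045650203,
   "0.01": 0.2538004040942341
  },
  "16": {
   "0.2": 0.175864649875566,
   "0.15": 0.18426592907213388,
   "0.1": 0.19540624085874367,
   "0.05": 0.21292440233089607,
   "0.01": 0.2464082535868633
  },
  "17": {
   "0.2": 0.17062803333585755,
   "0.15": 0.17874998006418583,
   "0.1": 0.18959006622612096,
   "0.05": 0.20652166934327956,
   "0.01": 0.240613288940034
  },
  "18": {
   "0.2": 0.16659366945685053,
   "0.15": 0.17456502123663337,
   "0.1": 0.18504205225149378,
   "0.05": 0.20122124858371573,
   "0.01": 0.2343120995727726
  },
  "19": {
   "0.2": 0.16245407525415145,
   "0.15": 0.17029829649416314,
   "0.1": 0.18052971824470457,
   "0.05": 0.19668538975567812,
   "0.01": 0.22813204923586294
  },
  "20": {
   "0.2": 0.1588737676428302,
   "0.15": 0.1665945358411782,
   "0.1": 0.17661707269836596,
   "0.05": 0.19189580860937688,
   "0.01": 0.22299135045907495
  },
  "25": {
   "0.2": 0.1429124653259167,
   "0.15": 0.14985144341732878,
   "0.1": 0.1590085421276334,
   "0.05": 0.17293341670823234,
   "0.01": 0.20196549266709338
  },
  "30": {
   "0.2": 0.13118980042921888,
   "0.15": 0.13728783937315234,
   "0.1": 0.1455042301784677,
   "0.05": 0.1586478060026606,
   "0.01": 0.18503818617230383
  },
  "35": {
   "0.2": 0.12198526887892962,
   "0.15": 0.12773217024671576,
   "0.1": 0.13527334999642646,
   "0.05": 0.14729164453727278,
   "0.01": 0.17134572704103826
  },
  "40": {
   "0.2": 0.11434535892872756,
   "0.15": 0.1199579922217257,
   "0.1": 0.12732196888887579,
   "0.05": 0.13881587929065514,
   "0.01": 0.16174022156085052
  },
  "50": {
   "0.2": 0.10293679721471297,
   "0.15": 0.1079018360378839,
   "0.1": 0.11429706817853819,
   "0.05": 0.1246336472376353,
   "0.01": 0.14493122788974167
  },
  "60": {
   "0.2": 0.0944658826891818,
   "0.15": 0.09897929893046242,
   "0.1": 0.1049901438422153,
   "0.05": 0.11428818219837565,
   "0.01": 0.1324583074337338
  },
  "80": {
   "0.2": 0.08196821564350555,
   "0.15": 0.08595260187436224,
   "0.1": 0.09108335328370701,
   "0.05": 0.09920707201020174,
   "0.01": 0.1154769324610634
  },
  "100": {
   "0.2": 0.07360172493023917,
   "0.15": 0.07705718779547878,
   "0.1": 0.08163096889337984,
   "0.05": 0.08886064178097236,
   "0.01": 0.10400107004874047
  },
  "150": {
   "0.2": 0.06026764261944084,
   "0.15": 0.06325400362150582,
   "0.1": 0.06699496661204224,
   "0.05": 0.07297103814575642,
   "0.01": 0.08476250761809441
  },
  "200": {
   "0.2": 0.05239959689330758,
   "0.15": 0.05489278910437315,
   "0.1": 0.05821704531307171,
   "0.05": 0.06334774115545487,
   "0.01": 0.0739504347169138
  },
  "300": {
   "0.2": 0.04293000329953214,
   "0.15": 0.0449705141814782,
   "0.1": 0.04768832262778859,
   "0.05": 0.05195393135553834,
   "0.01": 0.06038580779653717
  },
  "500": {
   "0.2": 0.033278041885827704,
   "0.15": 0.03484896870216964,
   "0.1": 0.036952957365255605,
   "0.05": 0.04022271500670943,
   "0.01": 0.04695084896514365
  }
 }
}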