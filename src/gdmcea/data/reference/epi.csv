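age,t2dm_incidence_total,all_cause_mortality,t2dm_mortality,t2dm_prevalence,population
15,0.0002451862477686363,0.00012,0.00012,0.0017579108208949088,160000.0
16,0.0002677612643883869,0.00013190628954540387,0.00013190628954540387,0.0019405495974838779,159981.0
17,0.0002923631317833342,0.0001449939101802994,0.0001449939101802994,0.0021419068524263646,159960.0
18,0.0003191639229223904,0.0001593800724880238,0.0001593800724880238,0.002363845070923689,159937.0
19,0.00034834843003608926,0.00017519361657810606,0.00017519361657810606,0.002608399899430549,159911.0
20,0.0003801147405486768,0.00019257616595715106,0.00019257616595715106,0.0028777935939346493,159883.0
21,0.00041467476343531813,0.000211683395885731,0.000211683395885731,0.0031744489174524004,159852.0
22,0.00045225468610327117,0.00023268642758047993,0.00023268642758047993,0.0035010033497808748,159818.0
23,0.0004930953384055802,0.000255773360747637,0.000255773360747637,0.0038603234268270717,159781.0
24,0.0005374524365974408,0.00028115095817315706,0.00028115095817315706,0.004255518972298537,159740.0
25,0.0005855966759856,0.0003090464974563016,0.0003090464974563016,0.004689956920217011,159695.0
26,0.0006378136367767648,0.000339709806470532,0.000339709806470532,0.00516727435175208,159646.0
27,0.0006944034633163321,0.0003734155007809593,0.0003734155007809593,0.005691390283621787,159592.0
28,0.0007556802726839581,0.00041046544305629336,0.00041046544305629336,0.006266515647482296,159532.0
29,0.0008219712446919132,0.0004511914465013828,0.0004511914465013828,0.006897160790573779,159467.0
30,0.0008936153419923368,0.0004959582465218417,0.0004959582465218417,0.007588139708410685,159395.0
31,0.0009709616065855844,0.0005451667672345071,0.0005451667672345071,0.008344570092546836,159316.0
32,0.001054366977951615,0.0005992577120780558,0.0005992577120780558,0.009171868143818996,159229.0
33,0.001144193578789314,0.0006587155106807025,0.0006587155106807025,0.010075736969119438,159134.0
34,0.0012408054174989948,0.0007240726573324778,0.0007240726573324778,0.01106214725493549,159029.0
35,0.001344564462683884,0.0007959144799167319,0.0007959144799167319,0.012137308803398968,158914.0
36,0.0014558260547008423,0.0008748843820106333,0.0008748843820106333,0.013307631439027577,158787.0
37,0.0015749336332622802,0.0009616896051020525,0.0009616896051020525,0.014579673762376979,158648.0
38,0.0017022127788058538,0.0010571075625283042,0.0010571075625283042,0.01596007825914962,158496.0
39,0.0018379645891810341,0.001161992801862455,0.001161992801862455,0.01745549139129807,158328.0
40,0.0019824584422873754,0.0012772846581012014,0.0022991123845821624,0.01907246752353881,158145.0
41,0.002135924229434958,0.0014040156661949937,0.0025272281991509885,0.020817355898079655,157943.0
42,0.0022985441827376102,0.0015433208082616667,0.0027779774548710003,0.022696170384078045,157721.0
43,0.0024704444616113685,0.0016964476783000843,0.003053605820940152,0.02471444241336555,157478.0
44,0.002651686706642254,0.0018647676554373266,0.003356581779787188,0.026877058378572082,157211.0
45,0.0028422598112777353,0.002049788185775166,0.003689618734395299,0.029188083809017017,156918.0
46,0.0030420721999480536,0.00225316628283006,0.004055699309094108,0.031650577830626914,156597.0
47,0.0032509449318083223,0.00247672336747436,0.004458102061453848,0.03426640271319062,156244.0
48,0.0034686059684999526,0.002722461580282839,0.00490043084450911,0.03703603464015717,155858.0
49,0.0036946859483785424,0.0029925817123752168,0.00538664708227539,0.03995838310478118,155434.0
50,0.003928715795186875,0.0032895029153403818,0.005921105247612688,0.04303062741919922,154970.0
51,0.004170126453687067,0.0036158843667611564,0.006508591860170081,0.046248079579999365,154461.0
52,0.00441825098716678,0.00397464908537247,0.007154368353670446,0.049604083019582,153903.0
53,0.004672329192609337,0.004369010109137632,0.007864218196447737,0.053089956453093425,153293.0
54,0.004931514791296019,0.004802499270689209,0.008644498687240576,0.05669499100387273,152624.0
55,0.005194885140414549,0.005278998827842682,0.009502197890116828,0.06040650700770327,151893.0
56,0.0054614532915170395,0.005802776232460537,0.010444997218428967,0.06420997438200768,151093.0
57,0.005730182102498399,0.006378522349051064,0.011481340228291916,0.06808919731013456,150219.0
58,0.006,0.007011393465381327,0.012620508237686389,0.07202656043000354,149264.0
59,0.006269817897501601,0.007707057471344514,0.013872703448420126,0.0760033300033696,148221.0
60,0.006538546708482961,0.008471744619651988,0.015249140315373578,0.08,147083.0
61,0.0068051148595854516,0.009312303322954438,0.01676214598131799,0.0839966699966304,145843.0
62,0.007068485208703981,0.01023626148710212,0.018425270676783817,0.08797343956999648,144491.0
63,0.007327670807390664,0.011251893929834656,0.02025340907370238,0.09191080268986544,143019.0
64,0.007581749012833219,0.012368296488691186,0.022262933679644135,0.09579002561799232,141419.0
65,0.007829873546312933,0.01359546748183919,0.024471841467310542,0.09959349299229674,139681.0
66,0.008071284204813125,0.01494439725137169,0.026899915052469043,0.10330500899612727,137794.0
67,0.008305314051621458,0.016427166591008097,0.029568899863814575,0.10691004354690659,135751.0
68,0.008531394031500047,0.018057054939700827,0.03250269889146149,0.110395916980418,133539.0
69,0.008749055068191678,0.019848659310112034,0.03572758675820166,0.11375192042000062,131149.0
70,0.008957927800051946,0.021818025017064285,0.03927244503071572,0.11696937258080078,128572.0
71,0.009157740188722265,0.023982789376747887,0.0431690208781462,0.12004161689521882,125797.0
72,0.009348313293357747,0.02636233966363119,0.04745221139453614,0.12296396535984283,122816.0
73,0.009529555538388631,0.028977986739710197,0.05216037613147836,0.12573359728680938,119620.0
74,0.009701455817262391,0.03185315591109239,0.0573356806399663,0.1283494221693731,116204.0
75,0.009864075770565042,0.035013596721195375,0.06302447409815168,0.13081191619098298,112561.0
76,0.010017541557712626,0.03848761355943334,0.06927770440698001,0.1331229416214279,108688.0
77,0.010162035410818967,0.04230631915068525,0.07615137447123345,0.13528555758663444,104584.0
78,0.010297787221194147,0.04650391319575461,0.0837070437523583,0.13730382961592197,100252.0
79,0.010425066366737719,0.05111798865827945,0.092012379584903,0.13918264410192036,95696.0
80,0.010544173945299157,0.05618986844114733,0.1011417631940652,0.14092753247646117,90927.0
81,0.010655435537316117,0.06176497546763443,0.11117695584174198,0.14254450860870194,85959.0
82,0.010759194582501005,0.06789323948165467,0.12220783106697841,0.14403992174085037,80811.0
83,0.010855806421210687,0.07462954421035488,0.13433317957863877,0.14542032623762302,75506.0
84,0.010945633022048385,0.08203421889377156,0.1476615940087888,0.14669236856097242,70076.0
85,0.011029038393414415,0.09017357858360728,0.16231244145049312,0.14786269119660103,64557.0
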