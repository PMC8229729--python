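{
 "fit_seed": 844,
 "k_max": 4,
 "optimal_k": 2,
 "cell_ids": [
  "C0001",
  "C0002",
  "C0003",
  "C0004",
  "C0005",
  "C0006",
  "C0007",
  "C0008",
  "C0009",
  "C0010",
  "C0011",
  "C0012",
  "C0013",
  "C0014",
  "C0015",
  "C0016",
  "C0017",
  "C0018",
  "C0019",
  "C0020",
  "C0021",
  "C0022",
  "C0023",
  "C0024",
  "C0025",
  "C0026",
  "C0027",
  "C0028",
  "C0029",
  "C0030",
  "C0031",
  "C0032",
  "C0033",
  "C0034",
  "C0035",
  "C0036",
  "C0037",
  "C0038",
  "C0039",
  "C0040",
  "C0041",
  "C0042",
  "C0043",
  "C0044",
  "C0045",
  "C0046",
  "C0047",
  "C0048",
  "C0049",
  "C0050",
  "C0051",
  "C0052",
  "C0053",
  "C0054",
  "C0055",
  "C0056",
  "C0057",
  "C0058",
  "C0059",
  "C0060"
 ],
 "z_ordinates": [
  0.8533003230457673,
  4.075024135584398,
  1.0060924816279615,
  1.9478740202726088,
  2.471965669038903,
  3.3043972418174237,
  2.608282752519364,
  1.1747681894796567,
  2.3863208066988126,
  -1.701886139475239,
  0.4799064859332203,
  1.7459985258527506,
  7.050918273578848,
  -3.0593063286584092,
  2.9464920461808486,
  -3.681124074926724,
  -5.271150512003723,
  -2.9831319230757014,
  -0.29805581145011706,
  -0.7336512087151701,
  5.805945986602591,
  -3.010010531858351,
  -4.113014867684477,
  -5.235463983259507,
  3.222416544409813,
  4.919749295324902,
  -6.095371203001253,
  5.229423962228871,
  -1.478995368756855,
  -5.8168640170365755,
  4.33238908703273,
  5.177659413740327,
  -4.942708698421126,
  5.874789653822656,
  5.501374797854659,
  5.157745910512835,
  -0.7359276999450202,
  -3.8923780397596603,
  4.607559752849008,
  -2.122058193544467,
  -2.7810086757132138,
  4.363906592249548,
  -3.867567793510072,
  -8.148992226812076,
  -5.999483667536896,
  2.8755506616341195,
  -3.6706555962822525,
  -0.940471562165843,
  -2.57520093914467,
  -2.83423554666612,
  -0.46430167783755194,
  -2.5990053661511965,
  1.6157017923479173,
  0.3895357038178061,
  0.4760491426972909,
  -2.1972903150619203,
  1.935123255588981,
  -2.089228918566383,
  3.7754397657048515,
  -3.973161383028856
 ],
 "residuals": [
  1.5241259194499426,
  -0.7365931076483605,
  -2.5806250345932202,
  -1.65995836906722,
  1.4729314548199346,
  -0.262816777271345,
  -0.16564143530262943,
  -1.0377366806826434,
  -1.2564876451028972,
  1.395517638974706,
  2.413828339595515,
  -1.604433150391201,
  0.6405428683272572,
  0.7390816339140986,
  0.3848130513229462,
  0.6792822451740665,
  0.047181332949550736,
  0.9892781133989335,
  0.2624686353779282,
  -0.1757523212161285,
  0.44737436606368686,
  1.017536533175539,
  -4.770760137334352,
  -0.7175578273794585,
  -0.3543447997193372,
  -1.1255431667231663,
  -0.24151465851187304,
  -0.2629576912597731,
  -0.06804570606620786,
  0.24323212143244,
  0.26309594787378465,
  -0.26302104294117346,
  -0.4638126839119261,
  -0.03381037832919809,
  -0.2190322334594219,
  -0.06125668494025582,
  -2.5655855040144298,
  -0.22748018065979814,
  -0.6047827277138795,
  1.2458481894598865,
  -2.716651402724242,
  -0.521318569128919,
  0.8461137266994587,
  2.798046510081053,
  1.1639771898381888,
  -0.2621950546337697,
  -3.7406787266734773,
  -2.9294765485725107,
  1.8583757202866025,
  -3.5103161938712133,
  2.013964050363011,
  1.1334102016190908,
  0.09322567690969485,
  -2.5792090299270485,
  -0.3934117384131923,
  -3.84300511848223,
  -2.5686567707980696,
  1.72142999685288,
  -1.4112607120811331,
  1.0474741580102167
 ],
 "cluster_labels": [
  1,
  1,
  0,
  0,
  1,
  1,
  1,
  0,
  0,
  1,
  1,
  1,
  1,
  1,
  1,
  1,
  1,
  1,
  1,
  1,
  1,
  1,
  0,
  1,
  1,
  1,
  1,
  1,
  1,
  1,
  1,
  1,
  1,
  1,
  1,
  1,
  0,
  1,
  1,
  1,
  0,
  1,
  1,
  1,
  1,
  1,
  0,
  0,
  1,
  0,
  1,
  1,
  1,
  0,
  1,
  0,
  0,
  1,
  1,
  1
 ],
 "ladder_spans": [
  3.3803425738306063,
  5.364873483643653
 ],
 "k_table_avg_mse": [
  3.01370904384666,
  0.7154418071622279,
  2.773546453889519,
  1.833353734682562
 ],
 "trace_cell": "C0008",
 "trace": {
  "candidates": [
   2.6934311381791844,
   8.049039778074562
  ],
  "selected_cluster": 0,
  "selected_value": 2.6934311381791844,
  "radius": 3.3803425738306063,
  "neighbor_counts": [
   8,
   16
  ],
  "betas": [
   0.9226190476190477,
   0.5342261904761905
  ],
  "fallback": false
 }
}
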