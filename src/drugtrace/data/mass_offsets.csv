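delta_mass,label,category,composition
14.015650,methylation,metabolism,CH2
-14.015650,demethylation,metabolism,CH2
28.031300,ethylation,metabolism,C2H4
-28.031300,de-ethylation,metabolism,C2H4
26.015650,vinylation,metabolism,C2H2
-26.015650,loss of C2H2,metabolism,C2H2
15.994915,oxidation,metabolism,O
-15.994915,deoxygenation,metabolism,O
31.989830,dioxidation,metabolism,O2
-31.989830,dideoxygenation,metabolism,O2
18.010565,hydration,metabolism,H2O
-18.010565,dehydration,metabolism,H2O
36.021130,dihydration,metabolism,H4O2
-36.021130,didehydration,metabolism,H4O2
2.015650,hydrogenation,metabolism,H2
-2.015650,dehydrogenation,metabolism,H2
176.032090,glucuronidation,metabolism,C6H8O6
-176.032090,deglucuronidation,metabolism,C6H8O6
162.052825,glycosylation,metabolism,C6H10O5
-162.052825,deglycosylation,metabolism,C6H10O5
42.010565,acetylation,metabolism,C2H2O
-42.010565,deacetylation,metabolism,C2H2O
79.956816,sulfation,metabolism,SO3
-79.956816,desulfation,metabolism,SO3
57.021464,glycine conjugation,metabolism,C2H3NO
107.004100,taurine conjugation,metabolism,C2H5NO2S
30.010565,hydroxymethylation,metabolism,CH2O
-30.010565,loss of CH2O,metabolism,CH2O
43.989830,carboxylation,metabolism,CO2
-43.989830,decarboxylation,metabolism,CO2
27.994915,formylation,metabolism,CO
-27.994915,loss of CO,metabolism,CO
-17.026549,deamination,metabolism,NH3
33.961028,chlorination,metabolism,
-33.961028,dechlorination,metabolism,
13.979265,oxidation and dehydrogenation,metabolism,
-13.979265,reduction and hydrogenation,metabolism,
21.981945,sodium adduct,adduct,
37.955882,potassium adduct,adduct,
37.946941,calcium adduct,adduct,
17.026549,ammonium adduct,adduct,NH3
41.026549,acetonitrile adduct,adduct,C2H3N
32.026215,methanol adduct,adduct,CH4O
46.005480,formic acid adduct,adduct,CH2O2
60.021130,acetic acid adduct,adduct,C2H4O2
1.003355,+1.00 isotope,isotope,
2.006710,+2.00 isotope,isotope,
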