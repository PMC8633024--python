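{
  "error:Robot-Computer(perceptual)": 0.008166210267386453,
  "influence-vs-0.5[Computer]": -0.2453138319617874,
  "influence-vs-0.5[Robot]": -0.14581093365360046,
  "influence:Robot-Computer(social)": 0.09950289830818698,
  "model1:Intercept[Computer]": -0.0659494877510289,
  "model1:Robot-Computer": -0.09857151550151094,
  "model1:distance[Computer]": -0.32083523457038227,
  "model1:distance:Robot-Computer": -0.04844888509103107,
  "model1:distance[Robot]": -0.36928411966141306,
  "model2:Intercept": 1.2961934908656814,
  "model2:partner_influence": 2.483514990021567,
  "model3:Intercept[Computer,Baseline]": 0.20217527576551694,
  "model3:Susceptible-Baseline[Computer]": -0.008944710368939781,
  "model3:Unsusceptible-Baseline[Computer]": -0.033235592721059054,
  "model3:Susceptible-Baseline,Robot-Computer": 0.028797974494381727,
  "model3:Unsusceptible-Baseline,Robot-Computer": 0.04604928775672567,
  "model3:Susceptible-Baseline[Robot]": 0.01985326412544175,
  "model3:Unsusceptible-Baseline[Robot]": 0.012813695035666383,
  "model4:Intercept[Computer,Baseline]": 0.2365984207580857,
  "model4:Susceptible-Baseline[Computer]": -0.010018923626250096,
  "model4:Unsusceptible-Baseline[Computer]": -0.024776136126632934,
  "model4:Susceptible-Baseline,Robot-Computer": 0.021070936478269676,
  "model4:Unsusceptible-Baseline,Robot-Computer": 0.02726704742171719,
  "model4:Susceptible-Baseline[Robot]": 0.011052012852019599,
  "model4:Unsusceptible-Baseline[Robot]": 0.002490911295084209,
  "model5:Intercept[Computer,Baseline]": -0.04116927200975382,
  "model5:Susceptible-Baseline[Computer]": 0.024760612244574223,
  "model5:Unsusceptible-Baseline[Computer]": 0.033584845049420275,
  "model5:Susceptible-Baseline,Robot-Computer": -0.015365698114400698,
  "model5:Unsusceptible-Baseline,Robot-Computer": -0.02889917502758383,
  "model5:Susceptible-Baseline[Robot]": 0.00939491413017349,
  "model5:Unsusceptible-Baseline[Robot]": 0.00468567002183639,
  "model5:Susceptible-Unsusceptible[Computer]": -0.00882423280484617,
  "model5:Susceptible-Unsusceptible,Robot-Computer": 0.013533476913183318,
  "model5:Susceptible-Unsusceptible[Robot]": 0.00470924410833708,
  "model6:Final-Preceding[Computer]": 0.07617758734116284,
  "model6:Final-Preceding,Robot-Computer": -0.12260898502093198,
  "model6:Final-Preceding[Robot]": -0.04643139767976899
}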