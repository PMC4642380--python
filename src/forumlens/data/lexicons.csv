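category,group,term
e-cigarette,subject matter,ecig
e-cigarette,subject matter,ecigs
e-cigarette,subject matter,e-cig
e-cigarette,subject matter,ecigarette
e-cigarette,subject matter,vape
e-cigarette,subject matter,vaping
e-cigarette,subject matter,vaper
e-cigarette,subject matter,atty
e-cigarette,subject matter,atomizer
e-cigarette,subject matter,carto
e-cigarette,subject matter,cartomizer
e-cigarette,subject matter,eliquid
e-cigarette,subject matter,e-liquid
hookah,subject matter,hookah
hookah,subject matter,waterpipe
hookah,subject matter,shisha
hookah,subject matter,mouthpiece
hookah,subject matter,hose
hookah,subject matter,bowl
symptoms,health,throat
symptoms,health,cough
symptoms,health,coughing
symptoms,health,migraine
symptoms,health,headache
symptoms,health,craving
symptoms,health,cravings
symptoms,health,dizzy
symptoms,health,nausea
quitting,health,quit
quitting,health,quitting
quitting,health,stigma
quitting,health,stink
quitting,health,stress
quitting,health,depression
quitting,health,anxiety
quitting,health,cold turkey
quitting,health,relapse
perceptions,health,toxic
perceptions,health,dangerous
perceptions,health,safe
perceptions,health,safety
perceptions,health,harmful
perceptions,health,harmless
practitioners,health,doctor
practitioners,health,doctors
practitioners,health,physician
practitioners,health,physicians
practitioners,health,therapist
practitioners,health,therapists
practitioners,health,counselor
practitioners,health,counselors
practitioners,health,nurse
social relationships,context,family
social relationships,context,friend
social relationships,context,friends
social relationships,context,children
social relationships,context,kids
social relationships,context,wife
social relationships,context,husband
setting,context,home
setting,context,bar
setting,context,party
setting,context,lounge
setting,context,restaurant
setting,context,cafe
time,context,morning
time,context,afternoon
time,context,evening
time,context,night
time,context,weekend
cost,context,cheap
cost,context,expensive
cost,context,price
cost,context,prices
cost,context,saving
cost,context,cost
cost,context,afford
sensory experience,context,hit
sensory experience,context,cloud
sensory experience,context,clouds
sensory experience,context,buzz
sensory experience,context,flavor
sensory experience,context,flavour
sensory experience,context,taste
sensory experience,context,throat hit
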